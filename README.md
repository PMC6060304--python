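# threadnet

Longitudinal network analysis of threaded online peer-support
communities — the kind of forum where people with long-term health
conditions ask questions, answer each other, and a tiny core of
"superusers" quietly holds the whole community together.

The input is a post log: one row per public post with its author,
timestamp, thread id, parent post and hierarchy level (a reply to a
level-*t* post sits at level *t*+1), plus an optional registry of all
registered users including the majority who never post. From that single
table the package computes:

* **Reply networks** — a directed edge u → v per reply u wrote to a post
  by v — and their cumulative weekly snapshots;
* **Component dynamics** — how posting users coalesce into a giant
  connected component over time;
* **Robustness** — how the largest component collapses under targeted
  removal of the best-connected users;
* **Rich-club analysis** — the density of ties among users of degree ≥ k,
  normalized by degree-preserving rewired nulls:
  ρ(k) = R(k)/⟨R_rand(k)⟩, with ρ(k) < 1 the *anti-rich-club* signature
  of hubs preferentially answering the poorly connected;
* **Posting rhythms** — the DFT power spectrum of daily posting volume;
* **Interposting times** — pooled per-user gap distributions for the top
  contributors;
* **Expertise z-scores** — with a answers (level ≥ 2), q questions
  (level 1), n = a + q and community answer probability P_a,
  z = (a − n·P_a)/√(n·P_a(1−P_a)), which reduces to (a − 2q)/√(2n) at
  P_a = 2/3;
* **Ego-network triads** — closed triads centered on thread starters,
  correlated with how much they contribute back to their own threads.

Real community extracts of this kind are not publicly deposited, so the
package ships a seeded synthetic-forum generator (`synthetic_forum`)
whose presets emulate the statistical structure such analyses rely on:
a lurker majority, heavy-tailed posts per user, a ~2:1 answer:question
mix, periodic daily intensity, hub-to-periphery reply mixing, and
root-poster follow-ups that close triads. See `docs/methods.md` for the
model and every convention.

## Worked example

```python
import threadnet as tn

log = tn.generate_forum(tn.preset_config("blf_like", seed=42))
view = tn.undirected_projection(tn.build_reply_network(log))

curve = tn.normalized_rich_club_curve(view, n_nulls=20, seed=7)
print(view.n_nodes, view.n_edges, round(curve.max_defined(), 3))

spectrum = tn.periodogram(tn.daily_counts(log))
print(spectrum.dominant_period)

zt = tn.z_score_table(log)
print(round(zt.p_a, 4))
```

prints

```
1945 7379 1.0
2.0
0.6639
```

meaning: the synthetic community's reply network ties 1,945 users
through 7,379 distinct pairs; the normalized rich-club coefficient never
exceeds 1 (its maximum sits exactly at the trivial threshold), i.e. the
well-connected core avoids itself and answers the periphery; the
dominant posting rhythm is the injected 2-day cycle; and the estimated
answer probability recovers the configured 2/3.

The numbered scripts under `analysis/` run the full study on both
bundled presets and write tidy CSVs to `results/tables/`:

```sh
python analysis/01_simulate.py          # dataset-description tables
python analysis/02_network_structure.py # components, removal, rich club
python analysis/03_activity_patterns.py # rhythms, superusers, gaps
python analysis/04_expertise_ego.py     # z-scores, ego triads
```

The same computations are available per stage from the command line
(`threadnet simulate|validate|summarize|build-network|components|removal|`
`richclub|periodicity|interposting|superusers|zscore|ego-triads|run`);
`threadnet run --preset blf_like --seed 42 --out-dir out/` executes the
whole pipeline and writes a manifest that makes the run reproducible
from one integer seed.

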