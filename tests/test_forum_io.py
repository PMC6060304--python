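"""I/O, validation and export round-trips for the post-log schema."""

from __future__ import annotations

import io

import networkx as nx
import pandas as pd
import pytest

import threadnet as tn
from threadnet.errors import (ConsistencyError, DanglingReferenceError,
                              ParameterError, SchemaError)
from threadnet.model import PostLog

TOY_CSV = """post_id,thread_id,parent_post_id,author_id,timestamp,level,author_role
p1,t1,,A,2020-01-01T00:00:00+00:00,1,user
p2,t1,p1,B,2020-01-02T00:00:00+00:00,2,user
p3,t1,p2,A,2020-01-03T00:00:00+00:00,3,user
p4,t2,,C,2020-01-04T00:00:00+00:00,1,user
p5,t1,p1,C,2020-01-05T00:00:00+00:00,2,user
"""


class TestRead:
    def test_toy_csv(self):
        log = tn.read_post_log(io.StringIO(TOY_CSV), "csv")
        assert len(log) == 5
        assert log.posting_users() == {"A", "B", "C"}
        assert [p.level for p in log.posts] == [1, 2, 3, 1, 2]

    def test_levels_recomputed_when_absent(self):
        csv = "\n".join(
            line.rsplit(",", 2)[0] + "," + line.rsplit(",", 1)[1]
            for line in TOY_CSV.strip().splitlines()
        )
        log = tn.read_post_log(io.StringIO(csv), "csv")
        assert [p.level for p in log.posts] == [1, 2, 3, 1, 2]

    def test_missing_column_names_it(self):
        with pytest.raises(SchemaError, match="author_id"):
            tn.read_post_log(io.StringIO("post_id,thread_id,parent_post_id,timestamp\nx,t,,2020-01-01T00:00:00+00:00\n"), "csv")

    def test_inconsistent_level_names_post(self):
        bad = TOY_CSV.replace("p3,t1,p2,A,2020-01-03T00:00:00+00:00,3", "p3,t1,p2,A,2020-01-03T00:00:00+00:00,2")
        with pytest.raises(ConsistencyError, match="p3"):
            tn.read_post_log(io.StringIO(bad), "csv")

    def test_dangling_parent_jsonl(self):
        lines = (
            '{"post_id": "p1", "thread_id": "t1", "parent_post_id": null, "author_id": "A", "timestamp": "2020-01-01T00:00:00+00:00"}\n'
            '{"post_id": "p2", "thread_id": "t1", "parent_post_id": "px", "author_id": "B", "timestamp": "2020-01-02T00:00:00+00:00"}\n'
        )
        with pytest.raises(DanglingReferenceError, match="px"):
            tn.read_post_log(io.StringIO(lines), "jsonl")

    def test_naive_timestamp_rejected(self):
        bad = TOY_CSV.replace("2020-01-01T00:00:00+00:00", "2020-01-01T00:00:00")
        with pytest.raises(SchemaError, match="offset"):
            tn.read_post_log(io.StringIO(bad), "csv")


class TestValidate:
    def test_toy_counts(self, toy_log):
        rep = tn.validate_post_log(toy_log)
        assert rep.ok
        assert rep.counts["n_posts"] == 5
        assert rep.counts["n_posting_users"] == 3
        # replies target p1 (twice) and p2; posts receiving >= 1 reply
        assert rep.counts["n_posts_with_reply"] == 2
        assert rep.counts["n_posts_no_reply"] == 3

    def test_lurker_counts(self, toy_log_with_lurkers):
        rep = tn.validate_post_log(toy_log_with_lurkers)
        assert rep.counts["n_lurkers"] == 2
        assert rep.counts["lurker_fraction"] == pytest.approx(0.4)

    def test_reports_level_violation_without_raising(self, toy_log):
        posts = list(toy_log.posts)
        bad = tn.Post("p6", "t1", "p3", "B", posts[-1].timestamp, level=9)
        rep = tn.validate_post_log(PostLog(posts=posts + [bad]))
        assert not rep.ok
        assert any(i.post_id == "p6" and i.rule == "level-chain" for i in rep.errors)

    def test_idempotent(self, toy_log):
        first = tn.validate_post_log(toy_log)
        second = tn.validate_post_log(toy_log)
        assert first.counts == second.counts and len(first.errors) == len(second.errors)


class TestRoundTrip:
    @pytest.mark.parametrize("fmt", ["csv", "jsonl"])
    def test_toy_round_trip(self, toy_log_with_lurkers, tmp_path, fmt):
        posts_f = tmp_path / f"posts.{fmt}"
        users_f = tmp_path / f"users.{fmt}"
        tn.write_post_log(toy_log_with_lurkers, posts_f, fmt, users_sink=users_f)
        back = tn.read_post_log(posts_f, fmt, users_source=users_f)
        assert back == toy_log_with_lurkers

    def test_empty_log_round_trip(self, tmp_path):
        empty = PostLog(posts=[])
        f = tmp_path / "empty.csv"
        tn.write_post_log(empty, f, "csv")
        assert tn.read_post_log(f, "csv") == empty

    def test_synthetic_round_trip_lossless(self, tmp_path):
        cfg = tn.SyntheticConfig(n_users=300, duration=120, base_rate=85.0,
                                 lurker_fraction=0.6, seed=5)
        log = tn.generate_forum(cfg)
        assert len(log) >= 9000
        posts_f, users_f = tmp_path / "p.csv", tmp_path / "u.csv"
        tn.write_post_log(log, posts_f, "csv", users_sink=users_f)
        assert tn.read_post_log(posts_f, "csv", users_source=users_f) == log

    def test_unknown_format(self, toy_log, tmp_path):
        with pytest.raises(ParameterError):
            tn.write_post_log(toy_log, tmp_path / "x.bin", "parquet")


class TestExport:
    def test_edge_csv_rows(self, toy_log, tmp_path):
        net = tn.build_reply_network(toy_log)
        out = tmp_path / "edges.csv"
        tn.export_network(net, out, "edge_csv")
        df = pd.read_csv(out)
        assert len(df) == 3
        assert set(map(tuple, df.values.tolist())) == {("B", "A", 1), ("A", "B", 1), ("C", "A", 1)}

    def test_empty_network_headers_only(self, tmp_path):
        net = tn.build_reply_network(PostLog(posts=[]))
        out = tmp_path / "edges.csv"
        tn.export_network(net, out, "edge_csv")
        assert pd.read_csv(out).empty

    def test_graphml_round_trip(self, toy_log, tmp_path):
        net = tn.build_reply_network(toy_log)
        out = tmp_path / "net.graphml"
        tn.export_network(net, out, "graphml")
        back = nx.read_graphml(out)
        assert back.number_of_nodes() == net.n_nodes
        assert back.number_of_edges() == net.n_edges

    def test_unknown_export_format(self, toy_log, tmp_path):
        with pytest.raises(ParameterError):
            tn.export_network(tn.build_reply_network(toy_log), tmp_path / "x", "gexf")
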