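"""Connectome containers, delimited I/O, and binarization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import connstage as cs
from connstage.core import ConnectomeValidationError, default_region_labels


def write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestReadAdjacency:
    def test_parses_single_edge(self, tmp_path):
        path = write(tmp_path, "a.csv", "0,2.5\n2.5,0\n")
        conn = cs.read_adjacency(path)
        assert conn.n_nodes == 2
        assert conn.weights[0, 1] == 2.5
        assert conn.region_labels == default_region_labels(2)

    def test_tab_delimiter_autodetected(self, tmp_path):
        path = write(tmp_path, "a.tsv", "0\t1.5\n1.5\t0\n")
        assert cs.read_adjacency(path).weights[1, 0] == 1.5

    def test_zero_matrix_is_valid_empty_graph(self, tmp_path):
        path = write(tmp_path, "z.csv", "0,0,0\n0,0,0\n0,0,0\n")
        conn = cs.read_adjacency(path)
        assert conn.weights.sum() == 0

    @pytest.mark.parametrize("text, fragment", [
        ("0,1\n2,0\n", "(0,1)"),            # asymmetry names the cell
        ("0,-1\n-1,0\n", "negative"),
        ("3,1\n1,0\n", "diagonal"),
        ("0,1,2\n1,0,3\n", "square"),
    ])
    def test_validation_failures_name_offence(self, tmp_path, text,
                                              fragment):
        path = write(tmp_path, "bad.csv", text)
        with pytest.raises(ConnectomeValidationError, match=None) as err:
            cs.read_adjacency(path)
        assert fragment in str(err.value)


class TestRoundTrip:
    def test_small_exact(self, tmp_path):
        conn = cs.Connectome("s", "G0", np.array([[0, 2.5], [2.5, 0]]))
        cs.write_adjacency(conn, tmp_path / "w.csv")
        back = cs.read_adjacency(tmp_path / "w.csv")
        assert np.array_equal(back.weights, conn.weights)

    def test_random_matrix_within_1e12(self, tmp_path):
        rng = np.random.default_rng(42)
        w = rng.lognormal(size=(10, 10))
        w = np.triu(w, 1)
        w = w + w.T
        conn = cs.Connectome("s", "G1", w)
        cs.write_adjacency(conn, tmp_path / "w.csv")
        back = cs.read_adjacency(tmp_path / "w.csv")
        assert np.abs(back.weights - conn.weights).max() < 1e-12

    def test_empty_matrix(self, tmp_path):
        conn = cs.Connectome("s", "G0", np.zeros((3, 3)))
        cs.write_adjacency(conn, tmp_path / "w.csv")
        assert cs.read_adjacency(tmp_path / "w.csv").weights.sum() == 0


class TestBinarize:
    def test_presence_at_zero_threshold(self):
        conn = cs.Connectome("s", "G0", np.array([[0, 2.5], [2.5, 0]]))
        graph = cs.binarize(conn)
        assert np.array_equal(graph.adjacency, [[0, 1], [1, 0]])
        assert np.array_equal(graph.features, np.eye(2))

    def test_threshold_drops_weak_edges(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.4
        w[1, 2] = w[2, 1] = 1.2
        graph = cs.binarize(cs.Connectome("s", "G0", w), threshold=0.5)
        expected = np.zeros((3, 3))
        expected[1, 2] = expected[2, 1] = 1
        assert np.array_equal(graph.adjacency, expected)

    def test_all_zero_weights(self):
        graph = cs.binarize(cs.Connectome("s", "G0", np.zeros((4, 4))))
        assert graph.adjacency.sum() == 0
        assert np.array_equal(graph.features, np.eye(4))

    def test_negative_threshold_rejected(self):
        conn = cs.Connectome("s", "G0", np.zeros((2, 2)))
        with pytest.raises(ValueError):
            cs.binarize(conn, threshold=-0.1)

    def test_idempotent_on_own_output(self):
        rng = np.random.default_rng(7)
        w = rng.lognormal(size=(8, 8))
        w = np.triu(w, 1) + np.triu(w, 1).T
        once = cs.binarize(cs.Connectome("s", "G0", w))
        again = cs.binarize(cs.Connectome("s", "G0", once.adjacency))
        assert np.array_equal(once.adjacency, again.adjacency)

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(7)
        w = rng.lognormal(size=(10, 10))
        w = np.triu(w, 1) + np.triu(w, 1).T
        conn = cs.Connectome("s", "G0", w)
        previous = cs.binarize(conn, 0.0).adjacency
        for t in (0.5, 1.0, 2.0, 5.0):
            current = cs.binarize(conn, t).adjacency
            # raising the threshold never adds edges
            assert np.all(current <= previous)
            previous = current


class TestManifest:
    def make_dataset(self, tmp_path, sizes=(2, 2, 2)):
        rng = np.random.default_rng(0)
        conns = []
        for g, size in zip(cs.GROUPS, sizes):
            for i in range(size):
                w = rng.lognormal(size=(5, 5))
                w = np.triu(w, 1) + np.triu(w, 1).T
                conns.append(cs.Connectome(f"{g}_{i}", g, w))
        return cs.write_dataset(conns, tmp_path), conns

    def test_round_trips_in_order(self, tmp_path):
        manifest_path, conns = self.make_dataset(tmp_path)
        manifest, loaded = cs.load_manifest(manifest_path)
        assert [c.subject_id for c in loaded] == \
            [c.subject_id for c in conns]
        assert manifest.n_nodes == 5
        assert np.abs(loaded[0].weights - conns[0].weights).max() < 1e-12

    def test_clinical_alias_labels_are_canonicalized(self, tmp_path):
        path = write(tmp_path, "m.tsv",
                     "subject_id\tgroup\tpath\ns1\tSCI\ta.csv\n")
        write(tmp_path, "a.csv", "0,1\n1,0\n")
        _, loaded = cs.load_manifest(path)
        assert loaded[0].group == "G0"

    def test_duplicate_ids_rejected(self, tmp_path):
        write(tmp_path, "a.csv", "0,1\n1,0\n")
        path = write(tmp_path, "m.tsv",
                     "subject_id\tgroup\tpath\n"
                     "s1\tG0\ta.csv\ns1\tG1\ta.csv\n")
        with pytest.raises(ConnectomeValidationError, match="duplicate"):
            cs.load_manifest(path)

    def test_unknown_group_rejected(self, tmp_path):
        write(tmp_path, "a.csv", "0,1\n1,0\n")
        path = write(tmp_path, "m.tsv",
                     "subject_id\tgroup\tpath\ns1\tG9\ta.csv\n")
        with pytest.raises(ConnectomeValidationError, match="group"):
            cs.load_manifest(path)

    def test_node_count_mismatch_rejected(self, tmp_path):
        write(tmp_path, "a.csv", "0,1\n1,0\n")
        write(tmp_path, "b.csv", "0,1,0\n1,0,0\n0,0,0\n")
        path = write(tmp_path, "m.tsv",
                     "subject_id\tgroup\tpath\n"
                     "s1\tG0\ta.csv\ns2\tG1\tb.csv\n")
        with pytest.raises(ConnectomeValidationError, match="mismatch"):
            cs.load_manifest(path)


@settings(derandomize=True, database=None, max_examples=30, deadline=None)
@given(
    weights=st.lists(st.floats(0, 10, allow_nan=False), min_size=6,
                     max_size=6),
    lo=st.floats(0, 5), hi=st.floats(0, 5),
)
def test_binarize_is_monotone_and_idempotent(weights, lo, hi):
    """For any weights and thresholds lo <= hi, the edge set at hi is a
    subset of the edge set at lo, and re-binarizing is the identity."""
    lo, hi = min(lo, hi), max(lo, hi)
    w = np.zeros((4, 4))
    w[np.triu_indices(4, 1)] = weights
    w = w + w.T
    conn = cs.Connectome("s", "G0", w)
    a_lo = cs.binarize(conn, lo).adjacency
    a_hi = cs.binarize(conn, hi).adjacency
    assert np.all(a_hi <= a_lo)
    rebinarized = cs.binarize(cs.Connectome("s", "G0", a_hi)).adjacency
    assert np.array_equal(rebinarized, a_hi)


def test_destrieux_labels_cover_both_hemispheres():
    labels = cs.destrieux_labels()
    assert len(labels) == 148
    assert len(set(labels)) == 148
    assert sum(lab.startswith("lh_") for lab in labels) == 74
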