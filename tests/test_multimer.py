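import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from oracles import rmsd_rotation_search
from plmmsa.errors import InvalidInputError
from plmmsa.msa_build import Msa, MsaRowMeta
from plmmsa.multimer import (
    RecycleState,
    block_diagonal_unpaired,
    build_paired_features,
    kabsch_rmsd,
    pair_msas,
    select_templates,
    should_stop,
)


def _chain(query, hits):
    """hits: list of (row, score, taxid)."""
    rows = [query] + [h[0] for h in hits]
    meta = [MsaRowMeta("query", 0.0, None)] + [
        MsaRowMeta(f"h{i}", h[1], h[2]) for i, h in enumerate(hits)
    ]
    return Msa(rows=rows, meta=meta)


class TestPairing:
    def test_worked_two_chain_example(self):
        # chain A: taxa {t1: 2 rows, t2: 1}; chain B: {t1: 1, t3: 1}
        a = _chain("AAAA", [
            ("CCCC", 9.0, "t1"), ("DDDD", 8.0, "t1"), ("EEEE", 7.0, "t2"),
        ])
        b = _chain("WWW", [("YYY", 5.0, "t1"), ("HHH", 4.0, "t3")])
        paired, unpaired = pair_msas([a, b])
        assert paired == ["CCCCYYY"]  # rank-1 pairing of the shared taxon
        assert unpaired == [[2, 3], [2]]

    def test_no_shared_taxa(self):
        a = _chain("AAAA", [("CCCC", 9.0, "t1")])
        b = _chain("WWW", [("YYY", 5.0, "t2")])
        paired, unpaired = pair_msas([a, b])
        assert paired == []
        assert unpaired == [[1], [1]]

    def test_identical_taxon_multisets_fully_paired(self):
        a = _chain("AAAA", [("CCCC", 9.0, "t1"), ("DDDD", 8.0, "t1")])
        b = _chain("WWW", [("YYY", 5.0, "t1"), ("HHH", 4.0, "t1")])
        paired, unpaired = pair_msas([a, b])
        assert len(paired) == 2
        assert unpaired == [[], []]

    def test_rows_without_taxid_stay_unpaired(self):
        a = _chain("AAAA", [("CCCC", 9.0, None), ("DDDD", 8.0, "t1")])
        b = _chain("WWW", [("YYY", 5.0, "t1")])
        paired, unpaired = pair_msas([a, b])
        assert paired == ["DDDDYYY"]
        assert unpaired == [[1], []]

    def test_single_chain_rejected(self):
        with pytest.raises(InvalidInputError):
            pair_msas([_chain("AAAA", [])])

    def test_conservation_on_random_instances(self, rng):
        taxa = ["t1", "t2", "t3", "t4", None]
        for _ in range(10):
            chains = []
            for L in (6, 4, 5)[: int(rng.integers(2, 4))]:
                n = int(rng.integers(0, 6))
                hits = [
                    ("".join(rng.choice(list("ACDE-"), size=L)).replace("-", "A"),
                     float(rng.uniform(1, 10)),
                     taxa[int(rng.integers(len(taxa)))])
                    for _ in range(n)
                ]
                chains.append(_chain("A" * L, hits))
            paired, unpaired = pair_msas(chains)
            # per chain: consumed + unpaired = all hit rows
            for ci, chain in enumerate(chains):
                consumed = (chain.depth - 1) - len(unpaired[ci])
                taxon_of = [m.taxid for m in chain.meta[1:]]
                assert consumed + len(unpaired[ci]) == len(taxon_of)
            # every paired row has the combined length
            total = sum(len(c.query_row) for c in chains)
            assert all(len(row) == total for row in paired)

    def test_three_chain_partial_taxon_gets_gap_fill(self):
        a = _chain("AAAA", [("CCCC", 9.0, "t1")])
        b = _chain("WWW", [("YYY", 5.0, "t1")])
        c = _chain("KK", [("RR", 3.0, "t9")])
        paired, unpaired = pair_msas([a, b, c])
        assert paired == ["CCCCYYY--"]  # chain C lacks t1, padded with gaps
        assert unpaired[2] == [1]


class TestBlockDiagonal:
    def test_shapes_and_padding(self):
        a = _chain("A" * 10, [("C" * 10, 1.0, None), ("D" * 10, 1.0, None)])
        b = _chain(
            "W" * 7, [("Y" * 7, 1.0, None), ("H" * 7, 1.0, None), ("N" * 7, 1.0, None)]
        )
        block = block_diagonal_unpaired([a, b], [[1, 2], [1, 2, 3]])
        assert len(block) == 5
        assert all(len(row) == 17 for row in block)
        assert block[0] == "C" * 10 + "-" * 7
        assert block[2] == "-" * 10 + "Y" * 7

    def test_one_chain_empty(self):
        a = _chain("AAAA", [])
        b = _chain("WWW", [("YYY", 1.0, None)])
        block = block_diagonal_unpaired([a, b], [[], [1]])
        assert block == ["----YYY"]

    def test_span_confinement_oracle(self, rng):
        lengths = (5, 8, 3)
        chains = [
            _chain("A" * L, [("C" * L, 1.0, None) for _ in range(int(rng.integers(1, 4)))])
            for L in lengths
        ]
        unpaired = [list(range(1, c.depth)) for c in chains]
        block = block_diagonal_unpaired(chains, unpaired)
        spans = [(0, 5), (5, 13), (13, 16)]
        row_chain = [ci for ci, u in enumerate(unpaired) for _ in u]
        for row, ci in zip(block, row_chain):
            lo, hi = spans[ci]
            for pos, ch in enumerate(row):
                inside = lo <= pos < hi
                assert (ch != "-") == inside

    def test_paired_plus_block_lengths_consistent(self):
        a = _chain("AAAA", [("CCCC", 9.0, "t1"), ("DDDD", 8.0, None)])
        b = _chain("WWW", [("YYY", 5.0, "t1")])
        feature = build_paired_features([a, b])
        assert feature.query_row == "AAAAWWW"
        assert all(len(r) == 7 for r in feature.paired_rows + feature.unpaired_block)
        assert len(feature.paired_rows) == 1 and len(feature.unpaired_block) == 1


class TestTemplates:
    def test_high_confidence_accepted(self):
        sel = select_templates([("m1", np.full(10, 90.0))])
        assert sel.accepted == ["m1"]

    def test_threshold_is_strict(self):
        sel = select_templates([("m1", np.full(10, 70.0))])
        assert sel.accepted == []

    def test_mean_against_independent_summation(self):
        arr = np.array([60.0, 70.0, 81.5])
        sel = select_templates([("m1", arr)])
        expected = sum(float(x) for x in arr) / 3  # 70.5
        assert sel.mean_plddt["m1"] == pytest.approx(expected)
        assert sel.accepted == ["m1"]

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidInputError):
            select_templates([("m1", np.array([50.0, 101.0]))])


class TestKabschRmsd:
    def test_identical_sets_zero(self, rng):
        A = rng.normal(size=(10, 3))
        assert kabsch_rmsd(A, A) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_transform_invariance(self, rng):
        A = rng.normal(size=(12, 3)) * 5
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        B = A @ R.T + np.array([5.0, 5.0, 5.0])
        assert kabsch_rmsd(A, B) == pytest.approx(0.0, abs=1e-9)

    def test_symmetry(self, rng):
        A = rng.normal(size=(8, 3))
        B = A + rng.normal(scale=0.5, size=(8, 3))
        assert kabsch_rmsd(A, B) == pytest.approx(kabsch_rmsd(B, A), abs=1e-9)

    def test_matches_rotation_search_oracle_on_four_points(self, rng):
        for _ in range(5):
            A = rng.normal(size=(4, 3)) * 3
            B = rng.normal(size=(4, 3)) * 3
            assert kabsch_rmsd(A, B) == pytest.approx(
                rmsd_rotation_search(A, B), abs=1e-3
            )

    def test_unsuperposed_frame_rmsd(self):
        A = np.zeros((2, 3))
        B = np.zeros((2, 3))
        B[:, 0] = 2.0  # pure translation
        assert kabsch_rmsd(A, B, superpose=False) == pytest.approx(2.0)
        assert kabsch_rmsd(A, B, superpose=True) == pytest.approx(0.0, abs=1e-9)

    def test_mismatched_counts_rejected(self):
        with pytest.raises(InvalidInputError):
            kabsch_rmsd(np.zeros((3, 3)), np.zeros((4, 3)))


class TestShouldStop:
    def test_first_iteration_never_stops(self, rng):
        state = RecycleState(iteration=0, current=rng.normal(size=(5, 3)))
        assert should_stop(state) is False

    def test_rigid_copy_stops(self, rng):
        A = rng.normal(size=(6, 3))
        R = Rotation.from_euler("x", 45, degrees=True).as_matrix()
        state = RecycleState(iteration=1, current=A @ R.T + 1.0, previous=A)
        assert should_stop(state, cutoff=1.0) is True

    def test_cutoff_is_strict(self, rng):
        A = rng.normal(size=(20, 3)) * 4
        B = A + rng.normal(scale=1.2, size=A.shape)
        r = kabsch_rmsd(A, B)
        state = RecycleState(iteration=1, current=B, previous=A)
        assert should_stop(state, cutoff=r) is False  # RMSD == cutoff: keep going
        assert should_stop(state, cutoff=r + 1e-9) is True

    def test_monotone_in_cutoff(self, rng):
        A = rng.normal(size=(10, 3)) * 4
        B = A + rng.normal(scale=0.8, size=A.shape)
        state = RecycleState(iteration=1, current=B, previous=A)
        stopped = [should_stop(state, cutoff=c) for c in (0.1, 0.5, 1.0, 2.0, 5.0)]
        assert stopped == sorted(stopped)  # once True, stays True
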