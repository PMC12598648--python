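import numpy as np
import pytest

from oracles import a3m_row_accounting
from plmmsa.encoder import average_pool
from plmmsa.errors import ConfigurationError, InvalidInputError
from plmmsa.msa_build import (
    AlignmentResult,
    Msa,
    MsaRowMeta,
    RetrievalParams,
    alignment_to_a3m_row,
    build_msa,
    neff,
    route_encoders,
)
from plmmsa.synthetic import FamilySpec, generate_decoys, generate_families
from plmmsa.vector_index import IvfSq8Index


def _msa(rows, scores=None):
    scores = scores or [0.0] * len(rows)
    meta = [MsaRowMeta(f"s{i}", s) for i, s in enumerate(scores)]
    return Msa(rows=rows, meta=meta)


class TestRouting:
    def test_short_query_uses_short_encoder_only(self):
        assert route_encoders(127, RetrievalParams()) == ["esm"]

    def test_boundary_length_uses_all(self):
        assert route_encoders(128, RetrievalParams()) == ["esm", "ankh"]

    def test_long_query_uses_all(self):
        # database length caps apply at build time, not at routing
        assert route_encoders(3000, RetrievalParams()) == ["esm", "ankh"]

    def test_empty_encoder_list_rejected(self):
        with pytest.raises(ConfigurationError):
            route_encoders(10, RetrievalParams(encoders=()))


class TestA3mRow:
    def test_identity_alignment(self):
        aln = AlignmentResult(pairs=[(0, 0), (1, 1), (2, 2)], score=3.0, mode="global")
        assert alignment_to_a3m_row(aln, 3, "KRW") == "KRW"

    def test_deletion_column(self):
        aln = AlignmentResult(pairs=[(0, 0), (2, 1)], score=2.0, mode="global")
        assert alignment_to_a3m_row(aln, 3, "KR") == "K-R"

    def test_insertion_lowercased_between_columns(self):
        aln = AlignmentResult(pairs=[(0, 0), (1, 3)], score=2.0, mode="global")
        row = alignment_to_a3m_row(aln, 2, "KWYR")
        assert row == "KwyR"
        assert a3m_row_accounting(row, 2, "KWYR")

    def test_column_accounting_on_random_alignments(self, rng):
        target = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(50):
            qlen = int(rng.integers(3, 10))
            k = int(rng.integers(1, min(qlen, 8)))
            qs = sorted(rng.choice(qlen, size=k, replace=False))
            ts = sorted(rng.choice(len(target), size=k, replace=False))
            aln = AlignmentResult(
                pairs=list(zip(map(int, qs), map(int, ts))), score=0.0, mode="global"
            )
            row = alignment_to_a3m_row(aln, qlen, target)
            assert a3m_row_accounting(row, qlen, target)

    def test_out_of_bounds_pair_rejected(self):
        aln = AlignmentResult(pairs=[(0, 5)], score=1.0, mode="global")
        with pytest.raises(InvalidInputError):
            alignment_to_a3m_row(aln, 3, "KR")


class TestNeff:
    def test_identical_rows_collapse_to_one(self):
        assert neff(_msa(["ACDEF"] * 6)) == pytest.approx(1.0)

    def test_all_distinct_rows_count_fully(self):
        rows = ["AAAAA", "CCCCC", "DDDDD", "EEEEE"]
        assert neff(_msa(rows)) == pytest.approx(4.0)

    def test_two_duplicate_pairs(self):
        rows = ["AAAAA", "AAAAA", "CCCCC", "CCCCC"]
        assert neff(_msa(rows)) == pytest.approx(2.0)

    def test_bounded_by_row_count(self, rng):
        alphabet = np.array(list("ACDEF-"))
        for _ in range(10):
            n = int(rng.integers(2, 8))
            hit_rows = ["".join(rng.choice(alphabet, size=6)) for _ in range(n - 1)]
            rows = ["ACDEFG"] + hit_rows
            value = neff(_msa(rows))
            assert 1.0 <= value <= n + 1e-12

    def test_insertions_ignored(self):
        # lowercase insertions are not match columns and must not affect Neff
        plain = _msa(["ACDEF", "ACDEF"])
        inserted = _msa(["ACDEF", "ACwwwDEF"])
        assert neff(plain) == neff(inserted)


class TestMsaInvariants:
    def test_gapped_query_row_rejected(self):
        with pytest.raises(InvalidInputError):
            _msa(["AC-EF", "ACDEF"])

    def test_column_count_violation_rejected(self):
        with pytest.raises(InvalidInputError):
            _msa(["ACDEF", "ACD"])


def _build_toy_db(records, enc, nlist=None, seed=0):
    vectors = [average_pool(enc(seq, sequence_id=sid)) for sid, seq in records]
    nlist = nlist or max(1, min(len(vectors) // 5, 20))
    return IvfSq8Index.build(vectors, nlist=nlist, seed=seed)


class TestBuildMsa:
    RETRIEVAL = RetrievalParams(top_k=100, encoders=("esm",), short_encoder="esm")

    def test_self_only_database(self, toy):
        query = "ACDEFGHIKLMNPQRSTVWY" * 2
        idx = _build_toy_db([("QUERY", query)], toy, nlist=1)
        msa, report = build_msa(
            "QUERY", query,
            indexes={"esm": idx}, encoders={"esm": toy},
            sequences={"QUERY": query},
            retrieval=self.RETRIEVAL,
        )
        assert msa.depth == 2
        assert msa.rows[1] == query  # exact self hit aligns end to end
        assert report["n_retrieved"] == 1 and report["n_kept"] == 1

    def test_family_recovered_and_decoys_rejected(self, toy, align_encoder):
        fam = generate_families(FamilySpec(
            n_families=1, members_per_family=10, ancestor_length=50,
            substitution_rate=0.1, indel_rate=0.02, seed=3,
        ))
        decoys = generate_decoys(50, (40, 60), seed=4)
        records = fam.records + decoys
        idx = _build_toy_db(records, toy, seed=0)
        query = fam.ancestors["F000"]
        msa, report = build_msa(
            "QUERY", query,
            indexes={"esm": idx}, encoders={"esm": toy},
            sequences=dict(records), align_encoder=align_encoder,
            retrieval=self.RETRIEVAL,
        )
        kept_ids = {m.sequence_id for m in msa.meta[1:]}
        assert sum(1 for i in kept_ids if i.startswith("F000")) >= 8
        assert not any(i.startswith("D") for i in kept_ids)
        assert report["n_retrieved"] >= report["n_kept"]

    def test_no_survivors_gives_query_only_msa(self, toy, align_encoder):
        decoys = generate_decoys(20, (40, 60), seed=5)
        idx = _build_toy_db(decoys, toy, nlist=4)
        query = "ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY"
        msa, report = build_msa(
            "QUERY", query,
            indexes={"esm": idx}, encoders={"esm": toy},
            sequences=dict(decoys), align_encoder=align_encoder,
            retrieval=self.RETRIEVAL,
        )
        assert msa.depth == 1
        assert neff(msa) == pytest.approx(1.0)

    def test_rows_sorted_by_score_and_meta_consistent(self, toy, align_encoder):
        fam = generate_families(FamilySpec(
            n_families=1, members_per_family=8, ancestor_length=40, seed=6,
        ))
        idx = _build_toy_db(fam.records, toy, nlist=2)
        msa, _ = build_msa(
            "QUERY", fam.ancestors["F000"],
            indexes={"esm": idx}, encoders={"esm": toy},
            sequences=dict(fam.records), align_encoder=align_encoder,
            retrieval=self.RETRIEVAL,
        )
        scores = [m.score for m in msa.meta[1:]]
        assert scores == sorted(scores, reverse=True)
        assert len(msa.rows) == len(msa.meta)

    def test_deterministic_rebuild(self, toy, align_encoder):
        fam = generate_families(FamilySpec(
            n_families=1, members_per_family=8, ancestor_length=40, seed=7,
        ))
        idx = _build_toy_db(fam.records, toy, nlist=2)
        args = dict(
            indexes={"esm": idx}, encoders={"esm": toy},
            sequences=dict(fam.records), align_encoder=align_encoder,
            retrieval=self.RETRIEVAL,
        )
        m1, _ = build_msa("QUERY", fam.ancestors["F000"], **args)
        m2, _ = build_msa("QUERY", fam.ancestors["F000"], **args)
        assert m1.rows == m2.rows

    def test_empty_query_rejected(self, toy):
        with pytest.raises(InvalidInputError):
            build_msa("q", "", indexes={}, encoders={}, sequences={})
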