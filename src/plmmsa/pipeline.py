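"""End-to-end pipeline: configuration, orchestration, run report.

``run_pipeline`` executes encode → route → search → align → filter →
assemble → Neff for the first query record against a FASTA database,
writing the A3M, a per-row metadata TSV and a JSON run report that echoes
every effective parameter and the per-stage counts (so any run can be
audited and reproduced byte-for-byte from its report).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import yaml

from .embedding_align import FilterParams
from .encoder import ToyEncoder, chunked_pool
from .errors import ConfigurationError, InvalidInputError
from .io import read_fasta, read_taxonomy_tsv, write_a3m, write_msa_metadata
from .msa_build import AlignParams, Msa, RetrievalParams, build_msa, neff
from .vector_index import IvfSq8Index, nlist_heuristic

logger = logging.getLogger("plmmsa")


@dataclass(frozen=True)
class EncoderConfig:
    """One toy-encoder variant (name, dimension, k-mer width, hash seed)."""

    name: str
    dim: int = 64
    k: int = 3
    seed: int = 0
    max_len: Optional[int] = None
    db_max_len: Optional[int] = None

    def build(self) -> ToyEncoder:
        return ToyEncoder(
            name=self.name, dim=self.dim, k=self.k, seed=self.seed,
            max_len=self.max_len, db_max_len=self.db_max_len,
        )


def _default_encoders() -> Tuple[EncoderConfig, ...]:
    # two complementary databases, mirroring a short-sequence specialist
    # (bounded window) and an unbounded encoder with a database length cap
    return (
        EncoderConfig(name="esm", dim=64, k=3, seed=101, max_len=1022),
        EncoderConfig(name="ankh", dim=96, k=4, seed=202, db_max_len=3000),
    )


@dataclass
class PipelineConfig:
    """Declarative configuration; CLI flags override file values, which
    override these defaults."""

    query_fasta: str = ""
    database_fasta: str = ""
    taxonomy_tsv: Optional[str] = None
    out_dir: str = "plmmsa_out"
    seed: int = 0
    encoders: Tuple[EncoderConfig, ...] = field(default_factory=_default_encoders)
    align_encoder: EncoderConfig = field(
        default_factory=lambda: EncoderConfig(name="align", dim=128, k=3, seed=303)
    )
    nlist: Optional[int] = None  # None = size heuristic, clamped to the database
    top_k: int = 1000
    short_len: int = 128
    short_encoder: str = "esm"
    nprobe: Optional[int] = None  # None = probe every cluster (exact at this scale)
    rel_frac: float = 0.2
    abs_min: float = 8.0
    align_mode: str = "semiglobal"
    gap_open: float = -0.5
    gap_extend: float = -0.1
    neff_threshold: float = 0.8
    tau: float = 0.05  # contrastive temperature, recorded for provenance

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        if "encoders" in raw:
            raw["encoders"] = tuple(EncoderConfig(**e) for e in raw["encoders"])
        if "align_encoder" in raw:
            raw["align_encoder"] = EncoderConfig(**raw["align_encoder"])
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> Dict:
        d = asdict(self)
        d["encoders"] = [asdict(e) for e in self.encoders]
        d["align_encoder"] = asdict(self.align_encoder)
        return d


def build_database_indexes(
    config: PipelineConfig, records: List[Tuple[str, str]]
) -> Tuple[Dict[str, IvfSq8Index], Dict[str, ToyEncoder], Dict[str, int]]:
    """Pool every admissible database sequence per encoder and build one
    IVF-SQ8 index per configured encoder."""
    if not records:
        raise InvalidInputError("database is empty")
    encoders = {e.name: e.build() for e in config.encoders}
    indexes: Dict[str, IvfSq8Index] = {}
    nlists: Dict[str, int] = {}
    for name, enc in encoders.items():
        cap = enc.spec.db_max_len
        admitted = [(sid, seq) for sid, seq in records if cap is None or len(seq) < cap]
        if not admitted:
            raise ConfigurationError(f"database for encoder {name!r} is empty")
        vectors = [chunked_pool(seq, enc, sequence_id=sid) for sid, seq in admitted]
        n = len(vectors)
        nlist = config.nlist if config.nlist is not None else nlist_heuristic(n)
        nlist = max(1, min(nlist, n))
        t0 = time.perf_counter()
        indexes[name] = IvfSq8Index.build(vectors, nlist=nlist, seed=config.seed)
        nlists[name] = nlist
        logger.info(
            "stage=index_build encoder=%s n=%d nlist=%d duration=%.3fs",
            name, n, nlist, time.perf_counter() - t0,
        )
    return indexes, encoders, nlists


def run_pipeline(config: PipelineConfig) -> Tuple[Msa, Dict]:
    """Run the full single-query pipeline and write outputs to out_dir."""
    if not config.query_fasta or not config.database_fasta:
        raise ConfigurationError("query_fasta and database_fasta are required")
    query_records = read_fasta(config.query_fasta)
    query_id, query_seq = query_records[0]
    if not query_seq:
        raise InvalidInputError("query sequence is empty")
    records = read_fasta(config.database_fasta)
    taxonomy = read_taxonomy_tsv(config.taxonomy_tsv) if config.taxonomy_tsv else None

    t0 = time.perf_counter()
    indexes, encoders, nlists = build_database_indexes(config, records)
    t_index = time.perf_counter() - t0

    retrieval = RetrievalParams(
        top_k=config.top_k,
        short_len=config.short_len,
        encoders=tuple(e.name for e in config.encoders),
        short_encoder=config.short_encoder,
        nprobe=config.nprobe,
    )
    filt = FilterParams(rel_frac=config.rel_frac, abs_min=config.abs_min)
    align = AlignParams(
        mode=config.align_mode, gap_open=config.gap_open, gap_extend=config.gap_extend
    )
    t0 = time.perf_counter()
    msa, report = build_msa(
        query_id=query_id,
        query_seq=query_seq,
        indexes=indexes,
        encoders=encoders,
        sequences=dict(records),
        align_encoder=config.align_encoder.build(),
        retrieval=retrieval,
        filt=filt,
        align=align,
        taxonomy=taxonomy,
    )
    t_msa = time.perf_counter() - t0
    logger.info(
        "stage=msa_build retrieved=%d aligned=%d kept=%d duration=%.3fs",
        report["n_retrieved"], report["n_aligned"], report["n_kept"], t_msa,
    )

    report["neff"] = neff(msa, identity_threshold=config.neff_threshold)
    report["n_database"] = len(records)
    report["nlist"] = nlists
    report["config"] = config.to_dict()
    report["timings_s"] = {"index_build": round(t_index, 3), "msa_build": round(t_msa, 3)}

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_a3m(msa, str(out / f"{query_id}.a3m"))
    write_msa_metadata(msa, str(out / f"{query_id}.tsv"))
    report_clean = {k: v for k, v in report.items() if k != "timings_s"}
    with open(out / f"{query_id}.report.json", "w") as f:
        json.dump(report_clean, f, indent=2, sort_keys=True)
        f.write("\n")
    return msa, report
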