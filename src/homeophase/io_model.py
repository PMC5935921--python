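"""Domain types, file readers/writers, configuration and logging.

The pipeline analyses an allopolyploid genome as a set of homoeologous
chromosome pairs.  Within each pairing, chromosome ``X`` is the copy with
the higher global GC content and ``X'`` its counterpart; homoeologous gene
pairs straddle the two copies.  All stages exchange the types defined here:
plain dataclasses for genes, pairs and pairings, a thin wrapper around a
pandas DataFrame for the RPKM matrix, and a run-level configuration object
whose hash is stamped into every output table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

PIPELINE_VERSION = "0.1.0"

SUBGENOME_H = "Fso_h"
SUBGENOME_L = "Fso_l"

logger = logging.getLogger("homeophase")


def configure_logging(level: str = "INFO") -> None:
    """Attach a simple stderr handler to the package logger (CLI entry point)."""
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(getattr(logging, level.upper()))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

_VALID_BASES = set("ACGTN")


@dataclass(frozen=True)
class GeneRecord:
    """A protein-coding gene on one physical chromosome copy.

    Coordinates are 1-based inclusive (GFF3 convention) as read from files;
    ``order_index`` is the rank of the gene along its chromosome counted from
    the 5' terminus.  ``cds`` holds the spliced coding sequence and may be
    empty for records read from a coordinate table before sequences are
    attached.
    """

    gene_id: str
    chrom_id: str
    order_index: int
    start: int
    end: int
    strand: str = "+"
    cds: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} > end {self.end}")
        if self.order_index < 0:
            raise ValueError(f"gene {self.gene_id}: negative order_index")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if self.cds and (set(self.cds) - _VALID_BASES):
            bad = sorted(set(self.cds) - _VALID_BASES)
            raise ValueError(f"gene {self.gene_id}: invalid CDS characters {bad}")


@dataclass(frozen=True)
class HomoeologPair:
    """One homoeologous gene pair: ``gene_x`` on chromosome X, ``gene_x_prime`` on X'."""

    pair_id: str
    chrom_pair: str
    gene_x: str
    gene_x_prime: str

    def __post_init__(self) -> None:
        if self.gene_x == self.gene_x_prime:
            raise ValueError(f"pair {self.pair_id}: both members are {self.gene_x}")


@dataclass(frozen=True)
class ChromosomePairing:
    """A homoeologous chromosome pair; X is the higher-global-GC copy."""

    pair_name: str
    chrom_x: str
    chrom_x_prime: str
    global_gc_x: float = math.nan
    global_gc_x_prime: float = math.nan

    def __post_init__(self) -> None:
        if self.chrom_x == self.chrom_x_prime:
            raise ValueError(f"pairing {self.pair_name}: identical chromosome ids")
        if (
            not math.isnan(self.global_gc_x)
            and not math.isnan(self.global_gc_x_prime)
            and self.global_gc_x < self.global_gc_x_prime
        ):
            raise ValueError(
                f"pairing {self.pair_name}: chromosome X must carry the higher global GC"
            )


class ExpressionMatrix:
    """Per-gene RPKM values across an ordered set of time points.

    Thin wrapper around a DataFrame (index = gene_id, columns = timepoints)
    enforcing non-negativity and unique gene ids.
    """

    def __init__(self, df: pd.DataFrame):
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids in expression matrix: {dups}")
        values = df.to_numpy(dtype=float)
        if np.isnan(values).any():
            raise ValueError("expression matrix contains missing values")
        if (values < 0).any():
            raise ValueError("expression matrix contains negative RPKM values")
        self.df = df.astype(float)

    @property
    def genes(self) -> list[str]:
        return list(self.df.index)

    @property
    def timepoints(self) -> list[str]:
        return list(self.df.columns)

    def rpkm(self, gene_id: str, timepoint: str) -> float:
        return float(self.df.at[gene_id, timepoint])

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.df.index

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ExpressionMatrix) and self.df.equals(other.df)


@dataclass
class AnnotationTable:
    """gene_id -> set of pathway/GO term ids, with optional term labels."""

    gene_terms: dict[str, set[str]]
    term_labels: dict[str, str] = field(default_factory=dict)

    def genes_for_term(self, term: str) -> set[str]:
        return {g for g, ts in self.gene_terms.items() if term in ts}

    @property
    def terms(self) -> set[str]:
        out: set[str] = set()
        for ts in self.gene_terms.values():
            out |= ts
        return out


@dataclass
class RunConfig:
    """Tunable thresholds shared across stages.

    window            odd width (genes) of the dGC moving average
    expressed_threshold  RPKM above which a gene counts as expressed
    fold_threshold    RPKM ratio at or above which a pair is called biased
    min_flip_run      minimum run length (genes) for a dGC flip segment
    min_flip_effect   minimum mean |smoothed dGC - 1| within a flip segment
    promoter_length   bp extracted upstream of the TSS
    rpkm_strata       RPKM cutoffs for stratified bias reports
    fdr_level         Benjamini-Hochberg FDR level for enrichment outputs
    """

    window: int = 11
    expressed_threshold: float = 1.0
    fold_threshold: float = 2.0
    min_flip_run: int = 20
    min_flip_effect: float = 0.01
    promoter_length: int = 500
    rpkm_strata: tuple[float, ...] = (50.0, 100.0, 500.0)
    seed: int = 0
    fdr_level: float = 0.05

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError(f"window must be odd and >= 1, got {self.window}")
        for name in ("expressed_threshold", "fold_threshold", "min_flip_effect",
                     "promoter_length", "fdr_level"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.min_flip_run < 1:
            raise ValueError("min_flip_run must be >= 1")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha1(payload.encode()).hexdigest()[:10]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "rpkm_strata" in raw:
            raw["rpkm_strata"] = tuple(float(x) for x in raw["rpkm_strata"])
        return cls(**raw)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_cds_fasta(path: str | Path) -> dict[str, str]:
    """Read a CDS FASTA into ``{gene_id: sequence}``.

    Sequences are uppercased and U converted to T.  Duplicate record ids and
    empty files are hard errors.
    """
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seqs:
            raise ValueError(f"duplicate FASTA record id: {record.id}")
        seqs[record.id] = str(record.seq).upper().replace("U", "T")
    if not seqs:
        raise ValueError(f"no FASTA records found in {path}")
    return seqs


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    """Read gene coordinates from a TSV or GFF3 file.

    TSV columns: gene_id, chrom, start, end, strand and optionally
    order_index.  When order_index is absent, order along each chromosome is
    derived by sorting on start (ties broken by gene_id).
    """
    path = Path(path)
    if path.suffix.lower() in {".gff", ".gff3"}:
        df = _parse_gff3(path)
    else:
        df = _read_tsv(path, dtype={"gene_id": str, "chrom": str})
        required = {"gene_id", "chrom", "start", "end", "strand"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"gene table missing columns: {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene ids in gene table: {dups}")
    if "order_index" not in df.columns:
        df = df.sort_values(["chrom", "start", "gene_id"], kind="stable")
        df["order_index"] = df.groupby("chrom").cumcount()
    records = [
        GeneRecord(
            gene_id=row.gene_id,
            chrom_id=row.chrom,
            order_index=int(row.order_index),
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
        )
        for row in df.itertuples()
    ]
    _check_unique_order(records)
    return records


def _parse_gff3(path: Path) -> pd.DataFrame:
    cols = ["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes"]
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=cols, dtype={"seqid": str})
    df = df[df["type"].isin(["gene", "mRNA"])]
    if df.empty:
        raise ValueError(f"no gene features found in GFF3 {path}")

    def _gene_id(attrs: str) -> str:
        for part in attrs.split(";"):
            key, _, value = part.strip().partition("=")
            if key == "ID":
                return value
        raise ValueError(f"GFF3 attribute string without ID: {attrs!r}")

    out = pd.DataFrame(
        {
            "gene_id": df["attributes"].map(_gene_id),
            "chrom": df["seqid"],
            "start": df["start"].astype(int),
            "end": df["end"].astype(int),
            "strand": df["strand"],
        }
    )
    return out.reset_index(drop=True)


def _check_unique_order(records: Sequence[GeneRecord]) -> None:
    seen: dict[tuple[str, int], str] = {}
    for rec in records:
        key = (rec.chrom_id, rec.order_index)
        if key in seen:
            raise ValueError(
                f"duplicate order_index {rec.order_index} on {rec.chrom_id}: "
                f"{seen[key]} and {rec.gene_id}"
            )
        seen[key] = rec.gene_id


def attach_cds(records: Iterable[GeneRecord], cds: Mapping[str, str]) -> list[GeneRecord]:
    """Return copies of ``records`` with coding sequences filled in from ``cds``."""
    out = []
    for rec in records:
        if rec.gene_id not in cds:
            raise KeyError(f"no CDS for gene {rec.gene_id}")
        out.append(dataclasses.replace(rec, cds=cds[rec.gene_id]))
    return out


def read_pairing_table(path: str | Path) -> list[ChromosomePairing]:
    """Read the chromosome pairing table.

    Columns: pair_name, chrom_x, chrom_x_prime and optionally global_gc_x,
    global_gc_x_prime (fractions in [0, 1]).
    """
    df = _read_tsv(path, dtype={"pair_name": str, "chrom_x": str, "chrom_x_prime": str})
    required = {"pair_name", "chrom_x", "chrom_x_prime"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"pairing table missing columns: {sorted(missing)}")
    pairings = []
    for row in df.itertuples():
        pairings.append(
            ChromosomePairing(
                pair_name=row.pair_name,
                chrom_x=row.chrom_x,
                chrom_x_prime=row.chrom_x_prime,
                global_gc_x=float(getattr(row, "global_gc_x", math.nan)),
                global_gc_x_prime=float(getattr(row, "global_gc_x_prime", math.nan)),
            )
        )
    return pairings


def read_pair_table(
    path: str | Path,
    pairings: Sequence[ChromosomePairing] | None = None,
) -> tuple[list[HomoeologPair], list[ChromosomePairing]]:
    """Read the homoeologous gene-pair table.

    Columns: pair_id, chrom_pair, gene_x, gene_x_prime.  Pairs are returned
    grouped by chromosome pairing in file order.  If ``pairings`` is given,
    each pair's ``chrom_pair`` must name one of them; otherwise placeholder
    pairings are synthesised from the distinct ``chrom_pair`` values.
    """
    df = _read_tsv(path, dtype=str)
    required = {"pair_id", "chrom_pair", "gene_x", "gene_x_prime"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"pair table missing columns: {sorted(missing)}")
    if df.empty:
        logger.warning("pair table %s has an empty data section", path)
        return [], list(pairings or [])

    known = {p.pair_name: p for p in pairings} if pairings is not None else None
    seen_genes: dict[str, str] = {}
    pairs: list[HomoeologPair] = []
    for row in df.itertuples():
        if known is not None and row.chrom_pair not in known:
            raise ValueError(f"pair {row.pair_id}: unknown chromosome pairing {row.chrom_pair}")
        for gene in (row.gene_x, row.gene_x_prime):
            if gene in seen_genes:
                raise ValueError(
                    f"gene {gene} appears in two pairs: {seen_genes[gene]} and {row.pair_id}"
                )
            seen_genes[gene] = row.pair_id
        pairs.append(
            HomoeologPair(
                pair_id=row.pair_id,
                chrom_pair=row.chrom_pair,
                gene_x=row.gene_x,
                gene_x_prime=row.gene_x_prime,
            )
        )
    # group by pairing, preserving first-appearance order of pairings
    order = {name: i for i, name in enumerate(dict.fromkeys(p.chrom_pair for p in pairs))}
    pairs.sort(key=lambda p: order[p.chrom_pair])
    if known is None:
        out_pairings = [
            ChromosomePairing(pair_name=name, chrom_x=f"{name}_X", chrom_x_prime=f"{name}_Xp")
            for name in order
        ]
    else:
        out_pairings = list(pairings)
    return pairs, out_pairings


def read_expression_table(path: str | Path) -> ExpressionMatrix:
    """Read a TSV with first column gene_id and one column per timepoint."""
    df = _read_tsv(path, dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError("expression table needs a gene column and >= 1 timepoint column")
    gene_col = df.columns[0]
    if df[gene_col].duplicated().any():
        dups = df.loc[df[gene_col].duplicated(), gene_col].tolist()
        raise ValueError(f"duplicate gene rows in expression table: {dups}")
    df = df.set_index(gene_col)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric RPKM cell in {path}: {exc}") from exc
    return ExpressionMatrix(df)


def read_annotation_table(path: str | Path) -> AnnotationTable:
    """Read gene->term assignments (columns gene_id, term_id[, term_label])."""
    df = _read_tsv(path, dtype=str)
    required = {"gene_id", "term_id"}
    if required - set(df.columns):
        raise ValueError(f"annotation table missing columns: {sorted(required - set(df.columns))}")
    if (df["term_id"].fillna("") == "").any():
        raise ValueError("annotation table contains empty term ids")
    gene_terms: dict[str, set[str]] = {}
    labels: dict[str, str] = {}
    for row in df.itertuples():
        gene_terms.setdefault(row.gene_id, set()).add(row.term_id)
        if hasattr(row, "term_label") and isinstance(row.term_label, str):
            labels[row.term_id] = row.term_label
    return AnnotationTable(gene_terms=gene_terms, term_labels=labels)


def read_tss_table(path: str | Path) -> pd.DataFrame:
    """Read a TSS table (columns gene_id, chrom, pos, strand; pos 1-based)."""
    df = _read_tsv(path, dtype={"gene_id": str, "chrom": str})
    required = {"gene_id", "chrom", "pos", "strand"}
    if required - set(df.columns):
        raise ValueError(f"TSS table missing columns: {sorted(required - set(df.columns))}")
    df["pos"] = df["pos"].astype(int)
    return df


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_tsv(
    df: pd.DataFrame,
    path: str | Path,
    config: RunConfig | None = None,
    index: bool = False,
) -> None:
    """Write a result table as TSV with a commented provenance header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    stamp = f"# homeophase v{PIPELINE_VERSION}"
    if config is not None:
        stamp += f" config={config.config_hash()}"
    with open(path, "w") as fh:
        fh.write(stamp + "\n")
        df.to_csv(fh, sep="\t", index=index)


def write_json(obj, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, set):
            return sorted(o)
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(f"not JSON serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)
        fh.write("\n")


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.df.reset_index()
    df = df.rename(columns={df.columns[0]: "gene_id"})
    write_tsv(df, path)


def write_pair_table(pairs: Sequence[HomoeologPair], path: str | Path) -> None:
    df = pd.DataFrame(
        [(p.pair_id, p.chrom_pair, p.gene_x, p.gene_x_prime) for p in pairs],
        columns=["pair_id", "chrom_pair", "gene_x", "gene_x_prime"],
    )
    write_tsv(df, path)


def write_cds_fasta(cds: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for gene_id, seq in cds.items():
            fh.write(f">{gene_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def load_fsolaris_chromosome_counts() -> pd.DataFrame:
    """Load the packaged chromosome-level gene counts for *F. solaris*.

    One row per homoeologous chromosome pair (42 pairs) plus segment
    sub-rows for the Chr10 dGC flip-over; H/L columns are keyed by the
    dGC-defined subgenome of each copy.
    """
    path = Path(__file__).parent / "data" / "fsolaris_chromosomes.tsv"
    df = _read_tsv(path, dtype={"chromosome": str, "segment": str})
    df["segment"] = df["segment"].fillna("")
    return df
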