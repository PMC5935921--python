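"""Codon-usage tables and correlation-matrix PCA separating subgenomes.

Codon counts of homoeologous genes are summed into their chromosome copy
(or chromosome segment, or whole subgenome), expressed as per-mil
frequencies, standardized column-wise and decomposed by PCA on the
correlation matrix.  Factor loadings are eigenvector elements scaled by
the component standard deviation (sqrt of the eigenvalue), so the squared
loadings of a component sum to its eigenvalue.  In a genuinely
allopolyploid genome the second component separates the two members of
every homoeologous chromosome pair, with the high-dGC (Fso_h) copy scoring
higher; the first component mostly reflects per-chromosome gene content
and carries uniformly signed loadings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_model import (
    SUBGENOME_H,
    SUBGENOME_L,
    ChromosomePairing,
    GeneRecord,
    HomoeologPair,
    logger,
)
from .gc_phasing import DgcProfile, SubgenomeAssignment, _segment_regions
from .synthetic import CODONS, CODON_INDEX

# ---------------------------------------------------------------------------
# Codon counting and aggregation
# ---------------------------------------------------------------------------


@dataclass
class CodonUsageTable:
    """64-codon counts and per-mil frequencies for one unit."""

    unit_id: str
    counts: np.ndarray  # shape (64,), integer counts

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def per_mil(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            return np.zeros(64)
        return self.counts * 1000.0 / total

    def to_series(self) -> pd.Series:
        return pd.Series(self.per_mil, index=CODONS, name=self.unit_id)


def codon_counts(cds: str) -> np.ndarray:
    """Count the 64 codons of a CDS read in frame from position 1.

    Only complete codons are counted; codons containing N (or any
    non-ACGT base) are dropped with a warning.
    """
    if len(cds) < 3:
        raise ValueError(f"CDS shorter than one codon (length {len(cds)})")
    counts = np.zeros(64, dtype=np.int64)
    dropped = 0
    seq = cds.upper()
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        idx = CODON_INDEX.get(codon)
        if idx is None:
            dropped += 1
        else:
            counts[idx] += 1
    if dropped:
        logger.warning("dropped %d ambiguous codons from a CDS", dropped)
    return counts


def aggregate_usage(
    cds: Mapping[str, str], groups: Mapping[str, Sequence[str]]
) -> dict[str, CodonUsageTable]:
    """Sum per-gene codon counts into named units (chromosome, segment, ...)."""
    if not groups:
        raise ValueError("empty group map")
    out: dict[str, CodonUsageTable] = {}
    for unit, gene_ids in groups.items():
        counts = np.zeros(64, dtype=np.int64)
        for gid in gene_ids:
            if gid not in cds:
                raise KeyError(f"unit {unit}: unknown gene id {gid}")
            counts += codon_counts(cds[gid])
        out[unit] = CodonUsageTable(unit_id=unit, counts=counts)
    return out


def usage_matrix(tables: Mapping[str, CodonUsageTable]) -> pd.DataFrame:
    """Units x 64 per-mil frequency matrix."""
    return pd.DataFrame([t.to_series() for t in tables.values()])


def usage_ratio(table_h: CodonUsageTable, table_l: CodonUsageTable) -> pd.DataFrame:
    """Per-codon per-mil usage ratio Fso_h / Fso_l.

    Codons absent from both tables get an undefined (NaN) ratio; a zero
    denominator with a nonzero numerator yields +inf.  Both cases are
    flagged.
    """
    pm_h, pm_l = table_h.per_mil, table_l.per_mil
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = pm_h / pm_l
    flag = np.where(
        (pm_h == 0) & (pm_l == 0), "undefined",
        np.where(pm_l == 0, "infinite", ""),
    )
    ratio = np.where((pm_h == 0) & (pm_l == 0), np.nan, ratio)
    return pd.DataFrame(
        {"codon": CODONS, "per_mil_h": pm_h, "per_mil_l": pm_l, "ratio": ratio, "flag": flag}
    )


# ---------------------------------------------------------------------------
# PCA on the correlation matrix
# ---------------------------------------------------------------------------


@dataclass
class PcaResult:
    observation_ids: list[str]
    variables: list[str]  # retained codons (zero-variance columns dropped)
    scores: np.ndarray  # (n_obs, n_vars)
    eigenvalues: np.ndarray  # (n_vars,), non-increasing; sums to n_vars
    loadings: np.ndarray  # (n_vars, n_components) = eigenvector * sqrt(eigenvalue)
    explained_variance: np.ndarray

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.observation_ids, columns=cols)

    def loadings_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.loadings.shape[1])]
        return pd.DataFrame(self.loadings, index=self.variables, columns=cols)


def pca_correlation(
    matrix: pd.DataFrame,
    orient_groups: Mapping[str, str] | None = None,
) -> PcaResult:
    """PCA of standardized per-mil frequencies via the correlation matrix.

    Zero-variance columns are dropped (logged) before standardization.
    Component signs are fixed for reproducibility: PC1 so that its mean
    loading is negative; PC2 so that the mean score of observations mapped
    to Fso_h by ``orient_groups`` is at least that of Fso_l observations
    (when given); any remaining ambiguity so that the largest-|loading|
    element is positive.
    """
    if matrix.shape[0] < 3:
        raise ValueError(f"PCA needs >= 3 observations, got {matrix.shape[0]}")
    values = matrix.to_numpy(dtype=float)
    sd = values.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [c for c, k in zip(matrix.columns, keep) if not k]
        logger.info("dropping %d zero-variance codon columns: %s", len(dropped), dropped)
    values = values[:, keep]
    variables = [c for c, k in zip(matrix.columns, keep) if k]
    z = (values - values.mean(axis=0)) / values.std(axis=0, ddof=1)
    corr = (z.T @ z) / (z.shape[0] - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]

    scores = z @ eigvec
    # deterministic sign conventions, component by component
    for k in range(eigvec.shape[1]):
        flip = False
        if k == 0:
            flip = eigvec[:, 0].mean() > 0
        elif k == 1 and orient_groups is not None:
            obs_h = [i for i, o in enumerate(matrix.index) if orient_groups.get(o) == SUBGENOME_H]
            obs_l = [i for i, o in enumerate(matrix.index) if orient_groups.get(o) == SUBGENOME_L]
            if obs_h and obs_l:
                flip = scores[obs_h, 1].mean() < scores[obs_l, 1].mean()
            else:
                flip = eigvec[np.abs(eigvec[:, 1]).argmax(), 1] < 0
        else:
            flip = eigvec[np.abs(eigvec[:, k]).argmax(), k] < 0
        if flip:
            eigvec[:, k] *= -1
            scores[:, k] *= -1

    loadings = eigvec * np.sqrt(eigval)
    return PcaResult(
        observation_ids=list(matrix.index),
        variables=variables,
        scores=scores,
        eigenvalues=eigval,
        loadings=loadings,
        explained_variance=eigval / eigval.sum(),
    )


# ---------------------------------------------------------------------------
# Subgenome separation diagnostics
# ---------------------------------------------------------------------------


@dataclass
class SeparationResult:
    """How cleanly PC2 splits each homoeologous chromosome pair."""

    fraction_separated: float  # pairs whose Fso_h member scores higher on PC2
    deltas: pd.DataFrame  # pair_name, obs_h, obs_l, pc2_h, pc2_l, delta
    violations: list[str]
    ties: list[str]


def chromosome_units(
    assignment: SubgenomeAssignment, pairings: Sequence[ChromosomePairing]
) -> tuple[dict[str, str], dict[str, str]]:
    """Map each physical chromosome id to its majority subgenome and pairing."""
    labels: dict[str, str] = {}
    unit_pairing: dict[str, str] = {}
    for pairing in pairings:
        pa = assignment.pairings.get(pairing.pair_name)
        if pa is None:
            continue
        labels[pairing.chrom_x] = SUBGENOME_H if pa.x_is_h else SUBGENOME_L
        labels[pairing.chrom_x_prime] = SUBGENOME_L if pa.x_is_h else SUBGENOME_H
        unit_pairing[pairing.chrom_x] = pairing.pair_name
        unit_pairing[pairing.chrom_x_prime] = pairing.pair_name
    return labels, unit_pairing


def chromosome_usage(
    genes: Sequence[GeneRecord] | Mapping[str, GeneRecord],
    pairs: Sequence[HomoeologPair],
    homoeologous_only: bool = True,
) -> dict[str, CodonUsageTable]:
    """Per-chromosome codon usage over homoeologous genes (optionally all genes)."""
    gene_map = genes if isinstance(genes, Mapping) else {g.gene_id: g for g in genes}
    paired = {p.gene_x for p in pairs} | {p.gene_x_prime for p in pairs}
    groups: dict[str, list[str]] = {}
    cds: dict[str, str] = {}
    for rec in gene_map.values():
        if homoeologous_only and rec.gene_id not in paired:
            continue
        groups.setdefault(rec.chrom_id, []).append(rec.gene_id)
        cds[rec.gene_id] = rec.cds
    return aggregate_usage(cds, groups)


def separation_check(
    pca: PcaResult,
    unit_labels: Mapping[str, str],
    unit_pairing: Mapping[str, str],
) -> SeparationResult:
    """Fraction of chromosome pairs whose Fso_h member has the higher PC2 score."""
    pc2 = dict(zip(pca.observation_ids, pca.scores[:, 1]))
    by_pair: dict[str, dict[str, str]] = {}
    for obs in pca.observation_ids:
        if obs not in unit_pairing:
            continue
        by_pair.setdefault(unit_pairing[obs], {})[unit_labels[obs]] = obs
    rows = []
    violations, ties = [], []
    for pair_name, members in by_pair.items():
        if set(members) != {SUBGENOME_H, SUBGENOME_L}:
            raise ValueError(f"pairing {pair_name}: missing observation for one subgenome")
        obs_h, obs_l = members[SUBGENOME_H], members[SUBGENOME_L]
        delta = pc2[obs_h] - pc2[obs_l]
        rows.append((pair_name, obs_h, obs_l, pc2[obs_h], pc2[obs_l], delta))
        if delta == 0:
            ties.append(pair_name)
        elif delta < 0:
            violations.append(pair_name)
    if not rows:
        raise ValueError("no chromosome pairs among PCA observations")
    deltas = pd.DataFrame(
        rows, columns=["pair_name", "obs_h", "obs_l", "pc2_h", "pc2_l", "delta"]
    )
    n_sep = sum(1 for r in rows if r[5] > 0)
    return SeparationResult(
        fraction_separated=n_sep / len(rows),
        deltas=deltas,
        violations=violations,
        ties=ties,
    )


def trna_subgenome_summary(
    trna_table: pd.DataFrame,
    labels: Mapping[str, str],
) -> pd.DataFrame:
    """Join externally predicted tRNA genes to subgenome labels.

    ``trna_table`` needs columns chrom and anticodon (one row per predicted
    tRNA gene); ``labels`` maps chromosome ids to subgenomes.  Returns
    anticodon x subgenome copy-number counts, a reporting aid for comparing
    tRNA repertoires against codon-usage preferences.  tRNA gene prediction
    itself is external.
    """
    required = {"chrom", "anticodon"}
    if required - set(trna_table.columns):
        raise ValueError(f"tRNA table missing columns: {sorted(required - set(trna_table.columns))}")
    df = trna_table.copy()
    df["subgenome"] = df["chrom"].map(labels)
    if df["subgenome"].isna().any():
        missing = df.loc[df["subgenome"].isna(), "chrom"].unique().tolist()
        raise KeyError(f"chromosomes without subgenome label: {missing}")
    out = (
        df.groupby(["anticodon", "subgenome"]).size().unstack(fill_value=0).reset_index()
    )
    out.columns.name = None
    for col in (SUBGENOME_H, SUBGENOME_L):
        if col not in out.columns:
            out[col] = 0
    return out[["anticodon", SUBGENOME_H, SUBGENOME_L]]


def segment_pca(
    genes: Sequence[GeneRecord] | Mapping[str, GeneRecord],
    profiles: Mapping[str, DgcProfile],
    assignment: SubgenomeAssignment,
    segments: Mapping[str, Sequence[tuple[int, int]]] | None = None,
    min_genes: int = 5,
) -> tuple[PcaResult, dict[str, str]]:
    """PCA with chromosome segments as observation units.

    By default each pairing that carries flip segments is split at the flip
    boundaries into dGC-homogeneous regions (labelled A, B, ...); explicit
    ``segments`` (pair-series index ranges per pairing) override this, e.g.
    to split an unflipped chromosome in half.  Both copies contribute one
    unit per region; regions with fewer than ``min_genes`` genes are
    skipped with a warning.  Whole-chromosome units of every pairing are
    included as context, so the gene-content axis stays on PC1 and the
    segments project onto the subgenome axis (PC2).  Returns the PCA plus
    unit -> subgenome labels (from the assignment; a flipped region of the
    X copy clusters with the opposite subgenome).
    """
    gene_map = genes if isinstance(genes, Mapping) else {g.gene_id: g for g in genes}
    groups: dict[str, list[str]] = {}
    unit_labels: dict[str, str] = {}
    n_segment_units = 0
    # whole-chromosome context units
    for pair_name, profile in profiles.items():
        pa = assignment.pairings.get(pair_name)
        if pa is None:
            continue
        unit_x, unit_xp = f"{pair_name}:X", f"{pair_name}:Xp"
        groups[unit_x] = list(profile.gene_x_ids)
        groups[unit_xp] = list(profile.gene_x_prime_ids)
        unit_labels[unit_x] = SUBGENOME_H if pa.x_is_h else SUBGENOME_L
        unit_labels[unit_xp] = SUBGENOME_L if pa.x_is_h else SUBGENOME_H
    for pair_name, profile in profiles.items():
        pa = assignment.pairings.get(pair_name)
        if pa is None:
            continue
        if segments is not None:
            if pair_name not in segments:
                continue
            regions = [
                (a, b, pa.x_is_h) for (a, b) in segments[pair_name]
            ]
            # honour flips inside explicit ranges via per-position labels
            regions = [
                (a, b, assignment.labels[profile.gene_x_ids[a]] == SUBGENOME_H)
                for (a, b, _) in regions
            ]
        elif pa.flip_segments:
            regions = _segment_regions(profile, pa)
        else:
            continue
        for letter, (a, b, x_is_h_here) in zip("ABCDEFGH", regions):
            n = b - a + 1
            if n < min_genes:
                logger.warning(
                    "pairing %s segment %s has %d genes (< %d); skipped",
                    pair_name, letter, n, min_genes,
                )
                continue
            unit_x = f"{pair_name}:X_{letter}"
            unit_xp = f"{pair_name}:Xp_{letter}"
            groups[unit_x] = profile.gene_x_ids[a : b + 1]
            groups[unit_xp] = profile.gene_x_prime_ids[a : b + 1]
            unit_labels[unit_x] = SUBGENOME_H if x_is_h_here else SUBGENOME_L
            unit_labels[unit_xp] = SUBGENOME_L if x_is_h_here else SUBGENOME_H
            n_segment_units += 2
    if not n_segment_units:
        raise ValueError("no segments of sufficient size to analyse")
    cds = {gid: gene_map[gid].cds for gids in groups.values() for gid in gids}
    tables = aggregate_usage(cds, groups)
    pca = pca_correlation(usage_matrix(tables), orient_groups=unit_labels)
    return pca, unit_labels
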