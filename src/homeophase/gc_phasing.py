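"""Subgenome phasing from homoeologous GC-content ratios (dGC / dGC3).

For every homoeologous gene pair the GC content of each copy is expressed
relative to the pair mean::

    dGC_X  = GC_X  / ((GC_X + GC_X') / 2)
    dGC_X' = GC_X' / ((GC_X + GC_X') / 2)

so the two values sum to exactly 2 and a value above 1 marks the copy with
the higher GC.  Plotted in gene order along chromosome X and smoothed with
an 11-gene moving average, the high-dGC copies of nearly all pairs sit on
one physical chromosome of the pair: that chromosome is assigned to the
pseudo-parental subgenome Fso_h and its counterpart to Fso_l.  Extended
runs of reversed polarity (dGC flip-overs) mark post-hybridization
intergenomic rearrangements; genes inside such runs get the opposite
label.  The same machinery runs on third-codon-position GC (dGC3), which
carries roughly twice the compositional signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import (
    SUBGENOME_H,
    SUBGENOME_L,
    ChromosomePairing,
    GeneRecord,
    HomoeologPair,
    logger,
)

# ---------------------------------------------------------------------------
# Elementary composition measures
# ---------------------------------------------------------------------------


def gc_content(seq: str) -> float:
    """GC fraction of a nucleotide string; N bases are excluded entirely."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    gc = seq.count("G") + seq.count("C")
    total = gc + seq.count("A") + seq.count("T")
    if total == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return gc / total


def gc3_content(cds: str) -> float:
    """GC fraction over the third base of every complete codon.

    A trailing incomplete codon is ignored with a warning.
    """
    if len(cds) < 3:
        raise ValueError(f"CDS shorter than one codon (length {len(cds)})")
    if len(cds) % 3:
        logger.warning("CDS length %d not a multiple of 3; trailing bases ignored", len(cds))
    n_codons = len(cds) // 3
    third = cds.upper()[2 : 3 * n_codons : 3]
    return gc_content(third)


def dgc_pair(gc_x: float, gc_x_prime: float) -> tuple[float, float]:
    """dGC of both copies of a pair; the two returned values sum to 2."""
    mean = (gc_x + gc_x_prime) / 2.0
    if mean == 0:
        raise ValueError("both GC values are zero")
    return gc_x / mean, gc_x_prime / mean


def smooth_series(values: Sequence[float], window: int) -> np.ndarray:
    """Centered simple moving average with truncated windows at the edges.

    Output has the same length as the input; near an edge the mean is taken
    over whatever part of the centered window falls inside the series.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    arr = np.asarray(values, dtype=float)
    if window > arr.size:
        raise ValueError(f"window {window} exceeds series length {arr.size}")
    return (
        pd.Series(arr).rolling(window=window, center=True, min_periods=1).mean().to_numpy()
    )


# ---------------------------------------------------------------------------
# Per-chromosome-pair dGC profiles
# ---------------------------------------------------------------------------


@dataclass
class DgcProfile:
    """Ordered dGC / dGC3 series of one homoeologous chromosome pair.

    Pair order follows the order of appearance of the X-copy genes along
    chromosome X (genes transposed off their syntenic position still enter
    the X-ordered series).
    """

    pair_name: str
    pair_ids: list[str]
    gene_x_ids: list[str]
    gene_x_prime_ids: list[str]
    order_x: np.ndarray  # order_index of each X-copy gene on its chromosome
    order_x_prime: np.ndarray
    gc_x: np.ndarray
    gc_x_prime: np.ndarray
    dgc_x: np.ndarray
    dgc_x_prime: np.ndarray
    gc3_x: np.ndarray
    gc3_x_prime: np.ndarray
    dgc3_x: np.ndarray
    dgc3_x_prime: np.ndarray
    smoothed_dgc_x: np.ndarray
    smoothed_dgc3_x: np.ndarray
    window: int

    def __len__(self) -> int:
        return len(self.pair_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pair_id": self.pair_ids,
                "order": np.arange(len(self.pair_ids)),
                "gene_x": self.gene_x_ids,
                "gene_x_prime": self.gene_x_prime_ids,
                "gc_x": self.gc_x,
                "gc_x_prime": self.gc_x_prime,
                "dgc_x": self.dgc_x,
                "dgc_x_prime": self.dgc_x_prime,
                "gc3_x": self.gc3_x,
                "gc3_x_prime": self.gc3_x_prime,
                "dgc3_x": self.dgc3_x,
                "dgc3_x_prime": self.dgc3_x_prime,
                "smoothed_dgc_x": self.smoothed_dgc_x,
                "smoothed_dgc3_x": self.smoothed_dgc3_x,
            }
        )


def compute_dgc_profiles(
    genes: Sequence[GeneRecord] | Mapping[str, GeneRecord],
    pairs: Sequence[HomoeologPair],
    pairings: Sequence[ChromosomePairing],
    window: int = 11,
) -> dict[str, DgcProfile]:
    """Compute dGC and dGC3 profiles for every chromosome pairing.

    ``genes`` must carry coding sequences (dGC is computed on the coding
    region only).
    """
    gene_map = genes if isinstance(genes, Mapping) else {g.gene_id: g for g in genes}
    by_pairing: dict[str, list[HomoeologPair]] = {}
    for pair in pairs:
        by_pairing.setdefault(pair.chrom_pair, []).append(pair)

    profiles: dict[str, DgcProfile] = {}
    for pairing in pairings:
        members = by_pairing.get(pairing.pair_name, [])
        if not members:
            logger.warning("pairing %s has no homoeologous pairs", pairing.pair_name)
            continue
        for pair in members:
            for gid in (pair.gene_x, pair.gene_x_prime):
                if gid not in gene_map:
                    raise KeyError(f"pair {pair.pair_id}: gene {gid} missing from gene records")
        members = sorted(members, key=lambda p: gene_map[p.gene_x].order_index)
        gx = np.array([gc_content(gene_map[p.gene_x].cds) for p in members])
        gxp = np.array([gc_content(gene_map[p.gene_x_prime].cds) for p in members])
        g3x = np.array([gc3_content(gene_map[p.gene_x].cds) for p in members])
        g3xp = np.array([gc3_content(gene_map[p.gene_x_prime].cds) for p in members])
        mean = (gx + gxp) / 2.0
        mean3 = (g3x + g3xp) / 2.0
        dgc_x, dgc_xp = gx / mean, gxp / mean
        dgc3_x, dgc3_xp = g3x / mean3, g3xp / mean3
        w = min(window, len(members) if len(members) % 2 else len(members) - 1)
        w = max(w, 1)
        if w != window:
            logger.warning(
                "pairing %s: window reduced to %d (only %d pairs)",
                pairing.pair_name, w, len(members),
            )
        profiles[pairing.pair_name] = DgcProfile(
            pair_name=pairing.pair_name,
            pair_ids=[p.pair_id for p in members],
            gene_x_ids=[p.gene_x for p in members],
            gene_x_prime_ids=[p.gene_x_prime for p in members],
            order_x=np.array([gene_map[p.gene_x].order_index for p in members]),
            order_x_prime=np.array([gene_map[p.gene_x_prime].order_index for p in members]),
            gc_x=gx,
            gc_x_prime=gxp,
            dgc_x=dgc_x,
            dgc_x_prime=dgc_xp,
            gc3_x=g3x,
            gc3_x_prime=g3xp,
            dgc3_x=dgc3_x,
            dgc3_x_prime=dgc3_xp,
            smoothed_dgc_x=smooth_series(dgc_x, w),
            smoothed_dgc3_x=smooth_series(dgc3_x, w),
            window=w,
        )
    return profiles


# ---------------------------------------------------------------------------
# Subgenome assignment with flip-over detection
# ---------------------------------------------------------------------------


@dataclass
class FlipSegment:
    """A maximal run of reversed dGC polarity accepted as a rearrangement."""

    start_index: int  # position in the pair series, inclusive
    end_index: int  # inclusive
    mean_effect: float  # mean |smoothed dGC - 1| within the run
    n_genes: int


@dataclass
class PairingAssignment:
    pair_name: str
    x_is_h: bool  # majority polarity: True if chromosome X carries Fso_h
    flip_segments: list[FlipSegment] = field(default_factory=list)
    low_confidence: bool = False


@dataclass
class SubgenomeAssignment:
    """Per-gene-copy subgenome labels plus per-pairing flip segments."""

    labels: dict[str, str]  # gene_id -> Fso_h / Fso_l
    pairings: dict[str, PairingAssignment]

    def label(self, gene_id: str) -> str:
        return self.labels[gene_id]


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in ``mask`` as (start, end) inclusive."""
    runs = []
    start = None
    for i, val in enumerate(mask):
        if val and start is None:
            start = i
        elif not val and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(mask) - 1))
    return runs


def assign_subgenomes(
    pairings: Sequence[ChromosomePairing],
    profiles: Mapping[str, DgcProfile],
    min_run: int = 20,
    min_effect: float = 0.01,
    use_dgc3: bool = True,
) -> SubgenomeAssignment:
    """Assign every gene copy to Fso_h or Fso_l from smoothed dGC polarity.

    The majority polarity of the smoothed series sets the default label of
    each physical chromosome; maximal runs of opposite polarity at least
    ``min_run`` genes long with mean |smoothed dGC - 1| >= ``min_effect``
    become flip segments whose gene labels are swapped.  Brief reversals
    below these thresholds are treated as noise.

    By default polarity is read from the smoothed dGC3 series: the third
    codon position carries the full compositional signal when divergence is
    synonymous, and the default ``min_effect`` is calibrated to its scale.
    The two series are interchangeable in polarity (their smoothed signs
    agree almost everywhere); pass ``use_dgc3=False`` to segment on the
    full-CDS dGC series instead.
    """
    labels: dict[str, str] = {}
    out: dict[str, PairingAssignment] = {}
    for pairing in pairings:
        profile = profiles.get(pairing.pair_name)
        if profile is None:
            continue
        smoothed = profile.smoothed_dgc3_x if use_dgc3 else profile.smoothed_dgc_x
        polarity = np.sign(smoothed - 1.0)
        balance = polarity.sum()
        low_confidence = False
        if balance != 0:
            majority = 1.0 if balance > 0 else -1.0
        else:
            # tie: fall back on the mean raw dGC of the X copies
            raw = profile.dgc3_x if use_dgc3 else profile.dgc_x
            majority = 1.0 if raw.mean() >= 1.0 else -1.0
            low_confidence = True
        mixed = (polarity == -majority).any()
        if len(profile) < min_run and mixed:
            # too short to distinguish rearrangement from noise
            raw = profile.dgc3_x if use_dgc3 else profile.dgc_x
            majority = 1.0 if raw.mean() >= 1.0 else -1.0
            low_confidence = True
            logger.warning(
                "pairing %s: %d pairs with mixed polarity; labelled by mean dGC "
                "(low confidence)", pairing.pair_name, len(profile),
            )
            flips: list[FlipSegment] = []
        else:
            flips = []
            for start, end in _runs(polarity == -majority):
                n = end - start + 1
                effect = float(np.abs(smoothed[start : end + 1] - 1.0).mean())
                if n >= min_run and effect >= min_effect:
                    flips.append(
                        FlipSegment(start_index=start, end_index=end,
                                    mean_effect=effect, n_genes=n)
                    )
        x_is_h = majority > 0
        assignment = PairingAssignment(
            pair_name=pairing.pair_name,
            x_is_h=x_is_h,
            flip_segments=flips,
            low_confidence=low_confidence,
        )
        out[pairing.pair_name] = assignment
        in_flip = np.zeros(len(profile), dtype=bool)
        for seg in flips:
            in_flip[seg.start_index : seg.end_index + 1] = True
        for i in range(len(profile)):
            x_label_h = x_is_h ^ bool(in_flip[i])
            labels[profile.gene_x_ids[i]] = SUBGENOME_H if x_label_h else SUBGENOME_L
            labels[profile.gene_x_prime_ids[i]] = SUBGENOME_L if x_label_h else SUBGENOME_H
    return SubgenomeAssignment(labels=labels, pairings=out)


# ---------------------------------------------------------------------------
# Chromosome summaries and fractionation bias
# ---------------------------------------------------------------------------


def _percent(count: int, total: int) -> float:
    """Percentage to two decimals, round half-up."""
    if total == 0:
        return 0.0
    value = (Decimal(100) * Decimal(count) / Decimal(total)).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP
    )
    return float(value)


def _segment_regions(profile: DgcProfile, assignment: PairingAssignment) -> list[tuple[int, int, bool]]:
    """Partition the pair series at flip boundaries.

    Returns (start, end, x_is_h_here) triples covering the whole series.
    """
    cuts = sorted(
        {0, len(profile)}
        | {seg.start_index for seg in assignment.flip_segments}
        | {seg.end_index + 1 for seg in assignment.flip_segments}
    )
    in_flip = np.zeros(len(profile), dtype=bool)
    for seg in assignment.flip_segments:
        in_flip[seg.start_index : seg.end_index + 1] = True
    regions = []
    for a, b in zip(cuts[:-1], cuts[1:]):
        regions.append((a, b - 1, assignment.x_is_h ^ bool(in_flip[a])))
    return regions


def chromosome_summary(
    assignment: SubgenomeAssignment,
    genes: Sequence[GeneRecord] | Mapping[str, GeneRecord],
    pairs: Sequence[HomoeologPair],
    pairings: Sequence[ChromosomePairing],
    profiles: Mapping[str, DgcProfile],
) -> pd.DataFrame:
    """Per-chromosome-pair gene counts keyed by dGC-defined subgenome.

    One row per pairing; pairings with flip segments additionally get one
    sub-row per dGC-homogeneous segment (labelled A, B, ...), with H/L
    re-keyed by the segment's own polarity.  homoeologous + non-homoeologous
    = predicted within every row and side.
    """
    gene_map = genes if isinstance(genes, Mapping) else {g.gene_id: g for g in genes}
    paired_ids = {p.gene_x for p in pairs} | {p.gene_x_prime for p in pairs}
    genes_by_chrom: dict[str, list[GeneRecord]] = {}
    for rec in gene_map.values():
        genes_by_chrom.setdefault(rec.chrom_id, []).append(rec)

    rows = []
    for pairing in pairings:
        pa = assignment.pairings.get(pairing.pair_name)
        profile = profiles.get(pairing.pair_name)
        if pa is None or profile is None:
            continue
        chrom_genes_x = genes_by_chrom.get(pairing.chrom_x, [])
        chrom_genes_xp = genes_by_chrom.get(pairing.chrom_x_prime, [])

        def _counts(records: list[GeneRecord]) -> tuple[int, int, int]:
            pred = len(records)
            homo = sum(1 for r in records if r.gene_id in paired_ids)
            return pred, homo, pred - homo

        def _row(segment: str, x_is_h_here: bool,
                 recs_x: list[GeneRecord], recs_xp: list[GeneRecord],
                 gc_known: bool) -> dict:
            pred_x, homo_x, non_x = _counts(recs_x)
            pred_xp, homo_xp, non_xp = _counts(recs_xp)
            if x_is_h_here:
                h, l = (pred_x, homo_x, non_x), (pred_xp, homo_xp, non_xp)
                gc_h, gc_l = pairing.global_gc_x, pairing.global_gc_x_prime
            else:
                h, l = (pred_xp, homo_xp, non_xp), (pred_x, homo_x, non_x)
                gc_h, gc_l = pairing.global_gc_x_prime, pairing.global_gc_x
            return {
                "chromosome": pairing.pair_name,
                "segment": segment,
                "global_gc_h": gc_h if gc_known else np.nan,
                "global_gc_l": gc_l if gc_known else np.nan,
                "predicted_h": h[0],
                "predicted_l": l[0],
                "homoeologous_h": h[1],
                "homoeologous_l": l[1],
                "non_homoeologous_h": h[2],
                "non_homoeologous_l": l[2],
                "homoeologous_pct_h": _percent(h[1], h[0]),
                "homoeologous_pct_l": _percent(l[1], l[0]),
                "non_homoeologous_pct_h": _percent(h[2], h[0]),
                "non_homoeologous_pct_l": _percent(l[2], l[0]),
            }

        rows.append(_row("", pa.x_is_h, chrom_genes_x, chrom_genes_xp, gc_known=True))
        if pa.flip_segments:
            regions = _segment_regions(profile, pa)
            for letter, (a, b, x_is_h_here) in zip("ABCDEFGH", regions):
                lo_x = profile.order_x[a]
                hi_x = profile.order_x[b]
                seg_orders_xp = profile.order_x_prime[a : b + 1]
                lo_xp, hi_xp = seg_orders_xp.min(), seg_orders_xp.max()
                recs_x = [r for r in chrom_genes_x if lo_x <= r.order_index <= hi_x]
                recs_xp = [r for r in chrom_genes_xp if lo_xp <= r.order_index <= hi_xp]
                rows.append(_row(letter, x_is_h_here, recs_x, recs_xp, gc_known=False))
    return pd.DataFrame(rows)


@dataclass
class FractionationBias:
    """Direction of biased gene loss across chromosome pairs."""

    n_greater_h: int  # pairs with strictly more non-homoeologous genes on the Fso_h side
    n_greater_l: int
    n_ties: int
    exceptions: list[str]  # pairings where the Fso_l side has more
    ties: list[str]
    p_value: float  # exact two-sided sign test (ties dropped)


def fractionation_bias(summary: pd.DataFrame) -> FractionationBias:
    """Sign test for fractionation asymmetry between the two subgenomes.

    For pairings with flip segments, counts are summed over the dGC-defined
    segment sub-rows (each re-keyed by its own polarity) rather than taken
    from the whole-chromosome row.
    """
    if summary.empty:
        raise ValueError("empty chromosome summary")
    df = summary.copy()
    df["segment"] = df.get("segment", "").fillna("")
    has_segments = set(df.loc[df["segment"] != "", "chromosome"])
    greater_h: list[str] = []
    greater_l: list[str] = []
    ties: list[str] = []
    for chrom, grp in df.groupby("chromosome", sort=False):
        if chrom in has_segments:
            grp = grp[grp["segment"] != ""]
        else:
            grp = grp[grp["segment"] == ""]
        non_h = int(grp["non_homoeologous_h"].sum())
        non_l = int(grp["non_homoeologous_l"].sum())
        if non_h > non_l:
            greater_h.append(chrom)
        elif non_l > non_h:
            greater_l.append(chrom)
        else:
            ties.append(chrom)
    n_h, n_l = len(greater_h), len(greater_l)
    if n_h + n_l:
        p = float(stats.binomtest(n_h, n_h + n_l, 0.5, alternative="two-sided").pvalue)
    else:
        p = 1.0
    return FractionationBias(
        n_greater_h=n_h,
        n_greater_l=n_l,
        n_ties=len(ties),
        exceptions=greater_l,
        ties=ties,
        p_value=p,
    )
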