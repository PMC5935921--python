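"""Homoeolog expression bias: per-pair calls, consistency, synchrony, statistics.

A pair is biased at a time point when one copy's RPKM is at least
``fold`` times the other's (two-fold by default, threshold inclusive), or
when exactly one copy is expressed at all (RPKM >= 1) — the silenced case,
which is counted as biased but tracked separately.  Pairs where both
copies stay below the expressed threshold at every time point are removed
before analysis.  Downstream summaries track whether the direction of
bias is maintained across time points, whether the two copies' expression
profiles move synchronously, and whether particular RPKM strata or
annotated pathways are enriched for bias toward one subgenome.
log2 fold changes are oriented so that positive means toward Fso_h.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_model import (
    SUBGENOME_H,
    SUBGENOME_L,
    AnnotationTable,
    ExpressionMatrix,
    HomoeologPair,
    logger,
)

TOWARD_H = "toward_h"
TOWARD_L = "toward_l"
NEUTRAL = "neutral"
NOT_EXPRESSED = "not_expressed"


# ---------------------------------------------------------------------------
# Core per-pair calls
# ---------------------------------------------------------------------------


def filter_expressed_pairs(
    expr: ExpressionMatrix,
    pairs: Sequence[HomoeologPair],
    threshold: float = 1.0,
) -> tuple[list[HomoeologPair], list[HomoeologPair]]:
    """Drop pairs where both copies stay below ``threshold`` at every timepoint."""
    retained, removed = [], []
    for pair in pairs:
        for gid in (pair.gene_x, pair.gene_x_prime):
            if gid not in expr:
                raise KeyError(f"pair {pair.pair_id}: gene {gid} missing from expression matrix")
        vals_x = expr.df.loc[pair.gene_x].to_numpy()
        vals_xp = expr.df.loc[pair.gene_x_prime].to_numpy()
        if (vals_x < threshold).all() and (vals_xp < threshold).all():
            removed.append(pair)
        else:
            retained.append(pair)
    return retained, removed


def call_bias(
    rpkm_a: float,
    rpkm_b: float,
    threshold: float = 1.0,
    fold: float = 2.0,
) -> tuple[str, bool, float]:
    """Bias call for one pair at one timepoint: (direction, silenced, log2fc).

    Direction is ``toward_a`` / ``toward_b`` / ``neutral`` /
    ``not_expressed``; the fold threshold is inclusive ("two-fold or
    greater").  log2fc = log2(a/b) where both values are positive, NaN
    otherwise.
    """
    if rpkm_a < 0 or rpkm_b < 0:
        raise ValueError("RPKM values must be non-negative")
    log2fc = math.log2(rpkm_a / rpkm_b) if rpkm_a > 0 and rpkm_b > 0 else math.nan
    a_on, b_on = rpkm_a >= threshold, rpkm_b >= threshold
    if not a_on and not b_on:
        return NOT_EXPRESSED, False, log2fc
    if a_on != b_on:
        return ("toward_a" if a_on else "toward_b"), True, log2fc
    hi, lo = max(rpkm_a, rpkm_b), min(rpkm_a, rpkm_b)
    if lo == 0 or hi / lo >= fold:
        if rpkm_a == rpkm_b:
            return NEUTRAL, False, log2fc
        return ("toward_a" if rpkm_a > rpkm_b else "toward_b"), False, log2fc
    return NEUTRAL, False, log2fc


def call_bias_table(
    expr: ExpressionMatrix,
    pairs: Sequence[HomoeologPair],
    labels: Mapping[str, str],
    threshold: float = 1.0,
    fold: float = 2.0,
) -> pd.DataFrame:
    """Bias calls for every pair and timepoint, oriented by subgenome.

    ``labels`` maps gene ids to Fso_h / Fso_l (e.g. from a
    SubgenomeAssignment); log2fc is log2(RPKM of the Fso_h copy / RPKM of
    the Fso_l copy).
    """
    rows = []
    for pair in pairs:
        lab_x = labels[pair.gene_x]
        if lab_x == labels[pair.gene_x_prime]:
            raise ValueError(f"pair {pair.pair_id}: both copies labelled {lab_x}")
        h_gene = pair.gene_x if lab_x == SUBGENOME_H else pair.gene_x_prime
        l_gene = pair.gene_x_prime if lab_x == SUBGENOME_H else pair.gene_x
        for tp in expr.timepoints:
            rh, rl = expr.rpkm(h_gene, tp), expr.rpkm(l_gene, tp)
            direction, silenced, log2fc = call_bias(rh, rl, threshold, fold)
            direction = {"toward_a": TOWARD_H, "toward_b": TOWARD_L}.get(direction, direction)
            rows.append((pair.pair_id, tp, direction, silenced, log2fc, rh, rl))
    return pd.DataFrame(
        rows,
        columns=["pair_id", "timepoint", "direction", "silenced", "log2fc", "rpkm_h", "rpkm_l"],
    )


# ---------------------------------------------------------------------------
# Consistency and synchrony across timepoints
# ---------------------------------------------------------------------------


def consistency(calls: pd.DataFrame) -> pd.DataFrame:
    """Classify each pair by whether bias direction is maintained over time.

    Timepoints where the pair is not expressed are dropped (and flagged);
    ``consistent_h`` / ``consistent_l`` require the same non-neutral
    direction at every evaluated timepoint, all-neutral pairs are
    ``neutral``, anything else ``mixed`` (strict reading: biased at two
    timepoints and neutral at one is mixed).
    """
    rows = []
    for pair_id, grp in calls.groupby("pair_id", sort=False):
        dirs = [d for d in grp["direction"] if d != NOT_EXPRESSED]
        flagged = len(dirs) < len(grp)
        if not dirs:
            cls = "not_assessable"
        elif all(d == TOWARD_H for d in dirs):
            cls = "consistent_h"
        elif all(d == TOWARD_L for d in dirs):
            cls = "consistent_l"
        elif all(d == NEUTRAL for d in dirs):
            cls = "neutral"
        else:
            cls = "mixed"
        rows.append((pair_id, cls, flagged, len(dirs)))
    return pd.DataFrame(rows, columns=["pair_id", "class", "had_gaps", "n_evaluated"])


def synchrony(
    expr: ExpressionMatrix,
    pairs: Sequence[HomoeologPair],
    method: str = "sign-concordance",
    min_r: float = 0.8,
) -> pd.DataFrame:
    """Classify pairs as synchronized / unsynchronized across timepoints.

    ``sign-concordance``: synchronized iff the sign of the RPKM change
    between every consecutive pair of timepoints matches for both copies,
    with zero changes acting as wildcards (flagged degenerate).
    ``pearson``: synchronized iff the correlation of the two copies'
    profiles is >= ``min_r``.  Pairs with fewer than two timepoints or a
    constant-zero profile are not assessable.
    """
    if method not in {"sign-concordance", "pearson"}:
        raise ValueError(f"unknown synchrony method: {method}")
    rows = []
    for pair in pairs:
        a = expr.df.loc[pair.gene_x].to_numpy()
        b = expr.df.loc[pair.gene_x_prime].to_numpy()
        degenerate = False
        if len(a) < 2 or (a == 0).all() or (b == 0).all():
            cls = "not_assessable"
        elif method == "sign-concordance":
            da, db = np.sign(np.diff(a)), np.sign(np.diff(b))
            degenerate = bool((da == 0).any() or (db == 0).any())
            ok = (da == db) | (da == 0) | (db == 0)
            cls = "synchronized" if ok.all() else "unsynchronized"
        else:
            sa, sb = a.std(), b.std()
            if sa == 0 or sb == 0:
                cls = "not_assessable"
            else:
                r = float(np.corrcoef(a, b)[0, 1])
                cls = "synchronized" if r >= min_r else "unsynchronized"
        rows.append((pair.pair_id, cls, method, degenerate))
    return pd.DataFrame(rows, columns=["pair_id", "class", "method", "degenerate"])


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


def chisq_gof(
    observed: Sequence[float], expected_proportions: Sequence[float]
) -> tuple[float, int, float]:
    """Pearson chi-square goodness-of-fit: (statistic, df, p)."""
    obs = np.asarray(observed, dtype=float)
    props = np.asarray(expected_proportions, dtype=float)
    if obs.shape != props.shape:
        raise ValueError("observed and expected proportions differ in length")
    expected = props * obs.sum()
    if (expected <= 0).any():
        raise ValueError("zero expected cell in chi-square GOF")
    statistic, p = stats.chisquare(obs, expected)
    return float(statistic), len(obs) - 1, float(p)


def fisher_2x2(table: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table: (odds ratio, p).

    p sums the probabilities of all tables with the same margins whose
    hypergeometric probability does not exceed the observed one.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("fisher_2x2 expects a 2x2 table")
    if (arr < 0).any():
        raise ValueError("negative counts in 2x2 table")
    odds, p = stats.fisher_exact(arr, alternative="two-sided")
    return float(odds), float(p)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values (NaN-safe)."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


# ---------------------------------------------------------------------------
# Stratified and pathway-level reports
# ---------------------------------------------------------------------------


def strata_bias_report(
    calls: pd.DataFrame,
    cutoffs: Sequence[float] = (50.0, 100.0, 500.0),
    membership: str = "max",
) -> pd.DataFrame:
    """Bias-direction counts within high-expression strata.

    A pair belongs to a stratum at a timepoint when the larger (or, with
    ``membership='mean'``, the mean) of its two RPKM values exceeds the
    cutoff.  Silenced pairs are counted separately and excluded from the
    toward_h/toward_l comparison, which is tested against a 50:50 split by
    chi-square GOF.
    """
    if membership not in {"max", "mean"}:
        raise ValueError("membership must be 'max' or 'mean'")
    rows = []
    for tp, grp in calls.groupby("timepoint", sort=False):
        top = getattr(grp[["rpkm_h", "rpkm_l"]], membership)(axis=1)
        for cutoff in cutoffs:
            sel = grp[top > cutoff]
            unsil = sel[~sel["silenced"]]
            n_h = int((unsil["direction"] == TOWARD_H).sum())
            n_l = int((unsil["direction"] == TOWARD_L).sum())
            n_neutral = int((unsil["direction"] == NEUTRAL).sum())
            n_sil = int(sel["silenced"].sum())
            if n_h + n_l > 0:
                _, _, p = chisq_gof([n_h, n_l], [0.5, 0.5])
            else:
                p = np.nan
            rows.append((tp, cutoff, n_h, n_l, n_neutral, n_sil, p))
    return pd.DataFrame(
        rows,
        columns=["timepoint", "cutoff", "toward_h", "toward_l", "neutral", "silenced", "p_50_50"],
    )


def _pair_terms(
    pairs: Sequence[HomoeologPair], annotation: AnnotationTable
) -> dict[str, set[str]]:
    """Terms of a pair = union of the terms of its two copies."""
    out: dict[str, set[str]] = {}
    for pair in pairs:
        terms = annotation.gene_terms.get(pair.gene_x, set()) | annotation.gene_terms.get(
            pair.gene_x_prime, set()
        )
        if terms:
            out[pair.pair_id] = terms
    return out


def pathway_bias(
    calls: pd.DataFrame,
    pairs: Sequence[HomoeologPair],
    annotation: AnnotationTable,
    compartments: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-term, per-timepoint bias summary with exact/chi-square tests.

    Pairs whose two copies localise to different compartments are excluded
    when a compartment map is supplied.  For each term, timepoint and
    direction the 2x2 table (term vs background) x (toward that direction
    vs not) is tested with Fisher's exact test when any expected cell is
    below 5, otherwise Pearson's chi-square; q is BH-adjusted over all
    rows.
    """
    usable = list(pairs)
    if compartments is not None:
        kept = []
        for pair in usable:
            ca = compartments.get(pair.gene_x)
            cb = compartments.get(pair.gene_x_prime)
            if ca is not None and cb is not None and ca != cb:
                continue
            kept.append(pair)
        usable = kept
    pair_terms = _pair_terms(usable, annotation)
    usable_ids = {p.pair_id for p in usable}
    calls = calls[calls["pair_id"].isin(usable_ids)]

    rows = []
    for term in sorted({t for ts in pair_terms.values() for t in ts}):
        members = {pid for pid, ts in pair_terms.items() if term in ts}
        if not members:
            logger.warning("term %s has zero pairs; skipped", term)
            continue
        in_term = calls["pair_id"].isin(members)
        for tp, grp in calls.groupby("timepoint", sort=False):
            sel = grp[grp["pair_id"].isin(members)]
            if sel.empty:
                continue
            fc = sel["log2fc"].dropna()
            q1, med, q3 = (
                (fc.quantile(0.25), fc.median(), fc.quantile(0.75))
                if len(fc)
                else (np.nan, np.nan, np.nan)
            )
            bg = grp[~grp["pair_id"].isin(members)]
            for direction in (TOWARD_H, TOWARD_L):
                a = int((sel["direction"] == direction).sum())
                b = len(sel) - a
                c = int((bg["direction"] == direction).sum())
                d = len(bg) - c
                table = np.array([[a, b], [c, d]], dtype=float)
                total = table.sum()
                expected = np.outer(table.sum(1), table.sum(0)) / total if total else table
                if (expected < 5).any():
                    odds, p = fisher_2x2(table)
                    test = "fisher"
                else:
                    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
                    odds = (a * d) / (b * c) if b * c else np.inf
                    test = "chi2"
                rows.append(
                    (term, tp, direction, len(sel), a, c, len(bg), med, q1, q3,
                     float(odds), float(p), test)
                )
    df = pd.DataFrame(
        rows,
        columns=["term", "timepoint", "direction", "n_term_pairs", "n_term_toward",
                 "n_background_toward", "n_background_pairs", "log2fc_median",
                 "log2fc_q1", "log2fc_q3", "odds_ratio", "p", "test"],
    )
    if not df.empty:
        df["q"] = bh_adjust(df["p"])
    return df


def term_frequency_logratio(
    group_a: set[str],
    group_b: set[str],
    annotation: AnnotationTable,
) -> pd.DataFrame:
    """Per-term relative frequency in two gene groups and their log ratio.

    Terms present in only one group get an infinite log ratio, flagged.
    """
    if not group_a or not group_b:
        raise ValueError("both gene groups must be non-empty")
    rows = []
    terms = sorted(
        {t for g in group_a | group_b for t in annotation.gene_terms.get(g, set())}
    )
    for term in terms:
        carriers = annotation.genes_for_term(term)
        fa = len(carriers & group_a) / len(group_a)
        fb = len(carriers & group_b) / len(group_b)
        if fa > 0 and fb > 0:
            log_ratio, flag = math.log2(fa / fb), ""
        elif fa == 0 and fb == 0:
            log_ratio, flag = math.nan, "absent"
        else:
            log_ratio, flag = math.copysign(math.inf, fa - fb), "infinite"
        rows.append((term, fa, fb, log_ratio, flag))
    return pd.DataFrame(rows, columns=["term", "freq_a", "freq_b", "log_ratio", "flag"])
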