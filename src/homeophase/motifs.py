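"""Promoter extraction, IUPAC motif scanning and subgenome enrichment.

Promoters are the configured stretch (500 bp by default) immediately
upstream of each gene's transcription start site, on the gene's own
strand.  User-supplied degenerate motifs (IUPAC alphabet, e.g. TABASTA
where B = C/G/T and S = C/G) are scanned with overlapping matches
allowed.  Subgenome-biased motif distribution is tested with a 2x2
Fisher exact test per motif (BH-corrected), and the association between
motif presence in one copy of a pair and the direction of expression bias
is summarised with Welch's t-test using timepoints as replicates.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import SUBGENOME_H, SUBGENOME_L, HomoeologPair, logger
from .expression_bias import TOWARD_H, TOWARD_L, bh_adjust, fisher_2x2

IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Promoter extraction
# ---------------------------------------------------------------------------


@dataclass
class Promoter:
    gene_id: str
    chrom: str
    start: int  # 1-based inclusive, on the + strand of the chromosome
    end: int
    strand: str
    seq: str  # sense-strand promoter sequence (reverse-complemented for -)
    truncated: bool


@dataclass
class PromoterSet:
    promoters: dict[str, Promoter]

    def sequences(self) -> dict[str, str]:
        return {gid: p.seq for gid, p in self.promoters.items()}

    def to_bed(self) -> pd.DataFrame:
        """0-based half-open intervals (BED convention)."""
        rows = [
            (p.chrom, p.start - 1, p.end, p.gene_id, 0, p.strand)
            for p in self.promoters.values()
        ]
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


def extract_promoters(
    genome: Mapping[str, str],
    tss_table: pd.DataFrame,
    length: int = 500,
) -> PromoterSet:
    """Extract promoter sequences upstream of each TSS.

    For a plus-strand gene the promoter is [TSS-length, TSS-1]; for a
    minus-strand gene it is the reverse complement of [TSS+1, TSS+length].
    Intervals are clipped at chromosome bounds and flagged truncated.
    """
    out: dict[str, Promoter] = {}
    for row in tss_table.itertuples():
        if row.chrom not in genome:
            raise KeyError(f"gene {row.gene_id}: unknown chromosome {row.chrom}")
        chrom_seq = genome[row.chrom].upper()
        n = len(chrom_seq)
        if not (1 <= row.pos <= n):
            raise ValueError(
                f"gene {row.gene_id}: TSS {row.pos} outside chromosome {row.chrom} (length {n})"
            )
        if row.strand == "+":
            start, end = row.pos - length, row.pos - 1
        elif row.strand == "-":
            start, end = row.pos + 1, row.pos + length
        else:
            raise ValueError(f"gene {row.gene_id}: bad strand {row.strand!r}")
        clipped_start, clipped_end = max(1, start), min(n, end)
        truncated = (clipped_start, clipped_end) != (start, end)
        if clipped_start > clipped_end:
            seq = ""
            truncated = True
            clipped_start, clipped_end = row.pos, row.pos - 1  # empty interval
        else:
            seq = chrom_seq[clipped_start - 1 : clipped_end]
            if row.strand == "-":
                seq = reverse_complement(seq)
        out[row.gene_id] = Promoter(
            gene_id=row.gene_id, chrom=row.chrom, start=clipped_start,
            end=clipped_end, strand=row.strand, seq=seq, truncated=truncated,
        )
    return PromoterSet(promoters=out)


# ---------------------------------------------------------------------------
# IUPAC motif scanning
# ---------------------------------------------------------------------------


def _motif_regex(motif: str) -> re.Pattern:
    parts = []
    for letter in motif.upper():
        if letter not in IUPAC:
            raise ValueError(f"invalid IUPAC code {letter!r} in motif {motif}")
        allowed = IUPAC[letter]
        parts.append(allowed if len(allowed) == 1 else f"[{allowed}]")
    # lookahead so overlapping occurrences are all reported
    return re.compile(f"(?=({''.join(parts)}))")


def find_motif(seq: str, motif: str) -> list[int]:
    """1-based start positions of all (overlapping) motif matches in ``seq``."""
    pattern = _motif_regex(motif)
    return [m.start() + 1 for m in pattern.finditer(seq.upper())]


def scan_iupac(
    promoters: PromoterSet | Mapping[str, str],
    motif: str,
    strands: str = "given",
) -> pd.DataFrame:
    """Scan every promoter for an IUPAC motif.

    ``strands='given'`` scans the sense sequence only; ``'both'``
    additionally reports matches of the motif on the opposite strand
    (positions still on the sense sequence).  Returns one row per gene
    with all match positions and a presence flag.
    """
    if strands not in {"given", "both"}:
        raise ValueError("strands must be 'given' or 'both'")
    seqs = promoters.sequences() if isinstance(promoters, PromoterSet) else promoters
    rc = reverse_complement(motif)
    rows = []
    for gene_id, seq in seqs.items():
        positions = find_motif(seq, motif)
        if strands == "both":
            positions = sorted(set(positions) | set(find_motif(seq, rc)))
        rows.append((gene_id, motif, positions, len(positions) > 0, len(positions)))
    return pd.DataFrame(
        rows, columns=["gene_id", "motif", "positions", "present", "n_matches"]
    )


def scan_motifs(
    promoters: PromoterSet | Mapping[str, str],
    motif_list: Sequence[str],
    strands: str = "given",
) -> pd.DataFrame:
    return pd.concat(
        [scan_iupac(promoters, m, strands) for m in motif_list], ignore_index=True
    )


# ---------------------------------------------------------------------------
# Enrichment and bias association
# ---------------------------------------------------------------------------


def motif_subgenome_enrichment(
    occurrences: pd.DataFrame,
    labels: Mapping[str, str],
) -> pd.DataFrame:
    """Per-motif 2x2 test for biased distribution between subgenomes.

    Table: (subgenome Fso_h / Fso_l) x (motif present / absent), Fisher
    two-sided, BH-adjusted across motifs.  Motifs with no occurrence at
    all are skipped with a warning.
    """
    rows = []
    for motif, grp in occurrences.groupby("motif", sort=False):
        missing = [g for g in grp["gene_id"] if g not in labels]
        if missing:
            raise KeyError(f"genes without subgenome label: {missing[:5]}")
        is_h = grp["gene_id"].map(labels) == SUBGENOME_H
        present = grp["present"].astype(bool)
        if not present.any():
            logger.warning("motif %s has zero occurrences; skipped", motif)
            continue
        a = int((is_h & present).sum())
        b = int((is_h & ~present).sum())
        c = int((~is_h & present).sum())
        d = int((~is_h & ~present).sum())
        odds, p = fisher_2x2([[a, b], [c, d]])
        rows.append((motif, a, b, c, d, odds, p))
    df = pd.DataFrame(
        rows,
        columns=["motif", "h_present", "h_absent", "l_present", "l_absent", "odds_ratio", "p"],
    )
    if not df.empty:
        df["q"] = bh_adjust(df["p"])
    return df


def welch_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Welch's unequal-variance t-test, two-sided: (t, p).

    Guards the zero-variance corner scipy rejects: equal constant samples
    give (0, 1); unequal constant samples give (inf, 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("Welch's t-test needs >= 2 observations per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        return math.copysign(math.inf, x.mean() - y.mean()), 0.0
    se2 = vx / len(x) + vy / len(y)
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / (
        (vx / len(x)) ** 2 / (len(x) - 1) + (vy / len(y)) ** 2 / (len(y) - 1)
    )
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def motif_conditional_bias(
    occurrences: pd.DataFrame,
    calls: pd.DataFrame,
    pairs: Sequence[HomoeologPair],
    labels: Mapping[str, str],
) -> pd.DataFrame:
    """Bias direction counts conditioned on which copy carries the motif.

    Pairs are split by motif presence: in both promoters, only the Fso_h
    copy, or only the Fso_l copy.  Per category, biased-pair counts toward
    each subgenome are tallied per timepoint; timepoints act as replicates
    (n = number of timepoints) for mean, SD and a Welch t-test of
    toward_h vs toward_l counts.
    """
    timepoints = list(calls["timepoint"].unique())
    if len(timepoints) < 2:
        raise ValueError("motif_conditional_bias needs >= 2 timepoints as replicates")
    present = dict(zip(occurrences["gene_id"], occurrences["present"].astype(bool)))
    category_of: dict[str, str] = {}
    for pair in pairs:
        lab_x = labels[pair.gene_x]
        h_gene = pair.gene_x if lab_x == SUBGENOME_H else pair.gene_x_prime
        l_gene = pair.gene_x_prime if lab_x == SUBGENOME_H else pair.gene_x
        ph, pl = present.get(h_gene, False), present.get(l_gene, False)
        if ph and pl:
            category_of[pair.pair_id] = "both"
        elif ph:
            category_of[pair.pair_id] = "only_h"
        elif pl:
            category_of[pair.pair_id] = "only_l"
    rows = []
    for category in ("both", "only_h", "only_l"):
        members = {pid for pid, c in category_of.items() if c == category}
        sub = calls[calls["pair_id"].isin(members)]
        counts_h = [
            int((sub[sub["timepoint"] == tp]["direction"] == TOWARD_H).sum())
            for tp in timepoints
        ]
        counts_l = [
            int((sub[sub["timepoint"] == tp]["direction"] == TOWARD_L).sum())
            for tp in timepoints
        ]
        t, p = welch_t(counts_h, counts_l)
        rows.append(
            (
                category, len(members),
                float(np.mean(counts_h)), float(np.std(counts_h, ddof=1)),
                float(np.mean(counts_l)), float(np.std(counts_l, ddof=1)),
                t, p,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["category", "n_pairs", "mean_toward_h", "sd_toward_h",
                 "mean_toward_l", "sd_toward_l", "welch_t", "p"],
    )
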