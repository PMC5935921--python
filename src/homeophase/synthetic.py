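"""Synthetic allopolyploid genomes and expression matrices with truth labels.

The generator emulates the statistical structure the phasing pipeline
exploits in a real allopolyploid: two pseudo-parental subgenomes whose
coding sequences differ only in synonymous codon choice, with distinct
third-position GC (GC3) targets (defaults 49.2% vs 47.9%) and
Dirichlet-perturbed synonymous codon-usage profiles; homoeologous
chromosome pairs carrying ordered gene pairs plus subgenome-biased
fractionated singletons; occasional crossover events that swap the
subgenome identity of a terminal chromosome segment; and a three-time-point
RPKM matrix in which a configurable fraction of pairs is >= 2-fold biased
or silenced toward a chosen subgenome.

Within a pair both copies share one amino-acid sequence; divergence is
synonymous-only, which isolates the compositional signal (dGC, dGC3,
codon usage) from protein-level differences.  Every stochastic choice is
written to a truth sidecar so downstream stages can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .io_model import (
    SUBGENOME_H,
    SUBGENOME_L,
    ChromosomePairing,
    ExpressionMatrix,
    GeneRecord,
    HomoeologPair,
    write_cds_fasta,
    write_expression_table,
    write_json,
    write_pair_table,
    write_tsv,
)

CODONS: list[str] = [a + b + c for a in "TCAG" for b in "TCAG" for c in "TCAG"]
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}

# amino-acid families (synonymous codon sets) of the standard genetic code;
# index 20 is the stop "amino acid"
_STOPS = sorted(standard_dna_table.stop_codons)
_AA_NAMES = sorted(set(standard_dna_table.forward_table.values()))
AA_FAMILIES: list[list[str]] = [
    sorted(c for c, aa in standard_dna_table.forward_table.items() if aa == name)
    for name in _AA_NAMES
] + [_STOPS]
N_AA = len(_AA_NAMES)  # 20; families[N_AA] is the stop family
_MET = _AA_NAMES.index("M")


@dataclass
class SimulationParams:
    """Knobs of the synthetic allopolyploid.

    gc3_h / gc3_l are the target third-position GC fractions of the two
    subgenomes; codon_profile_divergence scales how far the synonymous
    codon-usage profiles of the subgenomes drift apart (Dirichlet
    concentration 1/divergence within each synonymous sub-family, GC3-split
    preserving).  divergent_codon_fraction is the share of codon positions
    at which the two copies of a pair are drawn independently (the rest are
    identical, mimicking shared ancestry); the subgenome GC3 split is
    amplified on divergent positions so per-subgenome GC3 expectations stay
    exact.  chrom_content_sd scales a one-dimensional amino-acid content
    gradient across chromosome pairs (the gene-content variation that
    dominates PC1 of real codon-usage PCA).  bias_fraction is the fraction
    of retained (not all-silent) pairs with biased expression, inclusive of
    the silencing_fraction that is realised as one-copy silencing.
    """

    n_chrom_pairs: int = 10
    genes_per_chrom: int = 300
    codons_per_gene: int = 400
    gc3_h: float = 0.492
    gc3_l: float = 0.479
    codon_profile_divergence: float = 0.15
    divergent_codon_fraction: float = 0.3
    chrom_content_sd: float = 0.8
    fractionation_rate: float = 0.08
    fractionation_bias_h: float = 0.65
    n_crossovers: int = 1
    crossover_min_offset: int = 50
    timepoints: tuple[str, ...] = ("48h", "96h", "144h")
    bias_fraction: float = 0.61
    consistent_bias_fraction: float = 0.7
    silencing_fraction: float = 0.05
    all_silent_fraction: float = 0.156
    expressed_threshold: float = 1.0
    expr_mean_log2: float = 3.0
    expr_sd_log2: float = 2.0
    timepoint_sd_log2: float = 0.75
    noise_sd_log2: float = 0.3

    def __post_init__(self) -> None:
        for name in ("gc3_h", "gc3_l"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        for name in (
            "fractionation_rate", "fractionation_bias_h", "bias_fraction",
            "consistent_bias_fraction", "silencing_fraction", "all_silent_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.codon_profile_divergence < 0:
            raise ValueError("codon_profile_divergence must be >= 0")
        if not (0.0 < self.divergent_codon_fraction <= 1.0):
            raise ValueError("divergent_codon_fraction must lie in (0, 1]")
        if self.chrom_content_sd < 0:
            raise ValueError("chrom_content_sd must be >= 0")
        if self.silencing_fraction > self.bias_fraction:
            raise ValueError(
                "silencing_fraction is counted within bias_fraction and cannot exceed it"
            )
        if self.codons_per_gene < 3:
            raise ValueError("codons_per_gene must be >= 3")
        if 2 * self.crossover_min_offset >= self.genes_per_chrom and self.n_crossovers:
            raise ValueError("crossover_min_offset too large for genes_per_chrom")


@dataclass
class TruthLabels:
    """Ground truth emitted alongside the synthetic genome."""

    gene_subgenome: dict[str, str]  # gene_id -> Fso_h / Fso_l
    breakpoints: dict[str, list[int]]  # pair_name -> pair-series indices of first flipped pair
    breakpoints_slot: dict[str, list[int]]  # same events in slot coordinates
    x_is_h: dict[str, bool]  # pair_name -> whether chromosome X starts as Fso_h
    codon_profiles: dict[str, np.ndarray]  # subgenome -> expected 64-codon probabilities
    # (exact for the realized amino-acid sequences and shared/divergent masks)
    gc3_targets: dict[str, float]


@dataclass
class SyntheticGenome:
    params: SimulationParams
    seed: int
    cds: dict[str, str]
    genes: list[GeneRecord]
    pairs: list[HomoeologPair]
    pairings: list[ChromosomePairing]
    truth: TruthLabels

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        write_cds_fasta(self.cds, out / "cds.fasta")
        write_pair_table(self.pairs, out / "pairs.tsv")
        write_tsv(
            pd.DataFrame(
                [
                    (p.pair_name, p.chrom_x, p.chrom_x_prime,
                     p.global_gc_x, p.global_gc_x_prime)
                    for p in self.pairings
                ],
                columns=["pair_name", "chrom_x", "chrom_x_prime",
                         "global_gc_x", "global_gc_x_prime"],
            ),
            out / "pairings.tsv",
        )
        write_tsv(
            pd.DataFrame(
                [
                    (g.gene_id, g.chrom_id, g.order_index, g.start, g.end, g.strand)
                    for g in self.genes
                ],
                columns=["gene_id", "chrom", "order_index", "start", "end", "strand"],
            ),
            out / "genes.tsv",
        )
        write_json(
            {
                "seed": self.seed,
                "gene_subgenome": self.truth.gene_subgenome,
                "breakpoints": self.truth.breakpoints,
                "breakpoints_slot": self.truth.breakpoints_slot,
                "x_is_h": self.truth.x_is_h,
                "gc3_targets": self.truth.gc3_targets,
            },
            out / "truth_labels.json",
        )


# ---------------------------------------------------------------------------
# Codon-usage profile construction
# ---------------------------------------------------------------------------
#
# Synonymous divergence is modelled at the third codon position only.  Codons
# are grouped into "boxes": members of one amino-acid family sharing their
# first two bases (e.g. the CTN box of leucine, the TTR box of leucine, the
# two-codon AAR box of lysine).  The two copies of a pair always share the
# box at every position; at divergent positions each copy redraws only the
# third base -- a GC-vs-AT split (tuned to the subgenome's GC3 target) plus
# Dirichlet within-subset weights.  Full-CDS GC differences between
# homoeologs are therefore exactly their third-position differences, as when
# divergence between progenitors is synonymous.


@dataclass(frozen=True)
class _Box:
    family: int
    codon_idx: tuple[int, ...]  # indices into CODONS
    gc_members: tuple[int, ...]  # positions within codon_idx with G/C third base
    at_members: tuple[int, ...]


def _build_boxes() -> tuple[list["_Box"], list[list[int]]]:
    boxes: list[_Box] = []
    family_boxes: list[list[int]] = [[] for _ in AA_FAMILIES]
    for fam_i, codons in enumerate(AA_FAMILIES):
        by_pos12: dict[str, list[str]] = {}
        for codon in codons:
            by_pos12.setdefault(codon[:2], []).append(codon)
        for pos12 in sorted(by_pos12):
            members = sorted(by_pos12[pos12])
            gc = tuple(i for i, c in enumerate(members) if c[2] in "GC")
            at = tuple(i for i, c in enumerate(members) if c[2] in "AT")
            family_boxes[fam_i].append(len(boxes))
            boxes.append(
                _Box(
                    family=fam_i,
                    codon_idx=tuple(CODON_INDEX[c] for c in members),
                    gc_members=gc,
                    at_members=at,
                )
            )
    return boxes, family_boxes


_BOXES, _FAMILY_BOXES = _build_boxes()
# per family: probability that a uniformly chosen box is fixed-GC / tunable
_P_FIXED_GC = np.array(
    [sum(1 for b in fb if not _BOXES[b].at_members) / len(fb) for fb in _FAMILY_BOXES]
)
_P_VARIABLE = np.array(
    [
        sum(1 for b in fb if _BOXES[b].at_members and _BOXES[b].gc_members) / len(fb)
        for fb in _FAMILY_BOXES
    ]
)


def _gc3_split_probability(
    gc3_target: float, codons_per_gene: int, p_aa: np.ndarray
) -> float:
    """P(GC third base | tunable box) hitting ``gc3_target``.

    A gene is one start codon (ATG, fixed G), ``codons_per_gene - 2`` middle
    amino acids drawn from ``p_aa`` (Met and Trp are fixed-GC boxes) and one
    stop codon (the TAR stop box is tunable, TGA is fixed-AT).  Solves
    E[GC3 over the gene] = gc3_target for the split probability.
    """
    L = codons_per_gene
    a_mid = float(p_aa @ _P_FIXED_GC[:N_AA])
    v_mid = float(p_aa @ _P_VARIABLE[:N_AA])
    a_stop, v_stop = _P_FIXED_GC[N_AA], _P_VARIABLE[N_AA]
    p = (gc3_target * L - 1 - a_mid * (L - 2) - a_stop) / (v_mid * (L - 2) + v_stop)
    if not (0.0 < p < 1.0):
        raise ValueError(
            f"gc3 target {gc3_target} unreachable with {codons_per_gene} codons per gene"
        )
    return p


def _box_inner_weights(
    divergence: float, rng: np.random.Generator
) -> list[dict[str, np.ndarray]]:
    """Within-subset third-base weights per box for one subgenome.

    Dirichlet(1/divergence) inside each GC-ending and AT-ending subset
    (uniform when divergence == 0), so the draw never changes a box's
    expected GC3.
    """
    out = []
    for box in _BOXES:
        entry = {}
        for key, members in (("gc", box.gc_members), ("at", box.at_members)):
            if not members:
                entry[key] = np.array([])
            elif len(members) == 1 or divergence == 0:
                entry[key] = np.full(len(members), 1.0 / len(members))
            else:
                entry[key] = rng.dirichlet(np.full(len(members), 1.0 / divergence))
        out.append(entry)
    return out


def _amplify_inner(
    mid: list[dict[str, np.ndarray]],
    sub: list[dict[str, np.ndarray]],
    rho: float,
    eps: float = 1e-6,
) -> list[dict[str, np.ndarray]]:
    """Within-subset weights for divergent positions: mid + (sub - mid) / rho.

    Clipped at ``eps`` and renormalised within each subset, which leaves the
    GC3 split untouched.
    """
    out = []
    for m, s in zip(mid, sub):
        entry = {}
        for key in ("gc", "at"):
            if m[key].size == 0:
                entry[key] = m[key]
                continue
            w = np.clip(m[key] + (s[key] - m[key]) / rho, eps, None)
            entry[key] = w / w.sum()
        out.append(entry)
    return out


def _box_probs(split_p: float, inner: list[dict[str, np.ndarray]]) -> list[np.ndarray]:
    """Per-box codon probabilities from a GC3 split and within-subset weights."""
    probs = []
    for box, w in zip(_BOXES, inner):
        v = np.zeros(len(box.codon_idx))
        if box.gc_members and box.at_members:
            v[list(box.gc_members)] = split_p * w["gc"]
            v[list(box.at_members)] = (1.0 - split_p) * w["at"]
        elif box.gc_members:
            v[list(box.gc_members)] = w["gc"]
        else:
            v[list(box.at_members)] = w["at"]
        probs.append(v)
    return probs


def _sample_box_matrix(aa: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Choose a synonymous box uniformly per position, given amino acids."""
    out = np.empty(aa.shape, dtype=np.int16)
    for fam_i, fb in enumerate(_FAMILY_BOXES):
        mask = aa == fam_i
        count = int(mask.sum())
        if not count:
            continue
        out[mask] = np.asarray(fb, dtype=np.int16)[rng.integers(0, len(fb), size=count)]
    return out


def _sample_codons_for_boxes(
    box_matrix: np.ndarray,
    box_probs: list[np.ndarray],
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw codon indices given per-position boxes and per-box probabilities."""
    out = np.empty(box_matrix.shape, dtype=np.int16)
    for b, box in enumerate(_BOXES):
        mask = box_matrix == b
        count = int(mask.sum())
        if not count:
            continue
        if len(box.codon_idx) == 1:
            out[mask] = box.codon_idx[0]
        else:
            idx = rng.choice(len(box.codon_idx), size=count, p=box_probs[b])
            out[mask] = np.asarray(box.codon_idx, dtype=np.int16)[idx]
    return out


def _expected_counts_for_boxes(
    box_counts: np.ndarray, box_probs: list[np.ndarray]
) -> np.ndarray:
    """Expected 64-codon counts from realized per-box position counts."""
    expected = np.zeros(64)
    for b, box in enumerate(_BOXES):
        expected[list(box.codon_idx)] += box_counts[b] * box_probs[b]
    return expected


_CODON_ARR = np.array(CODONS)


def _codon_rows_to_seqs(matrix: np.ndarray) -> list[str]:
    return ["".join(row) for row in _CODON_ARR[matrix]]


# ---------------------------------------------------------------------------
# Genome simulation
# ---------------------------------------------------------------------------


def simulate_genome(params: SimulationParams, seed: int) -> SyntheticGenome:
    """Generate an allopolyploid genome with known subgenome truth.

    Deterministic for a fixed (params, seed).
    """
    ss = np.random.SeedSequence(seed)
    rng_prof_h, rng_prof_l, rng_content, rng_layout, rng_aa, rng_mask, rng_codon = (
        np.random.default_rng(s) for s in ss.spawn(7)
    )
    rho = params.divergent_codon_fraction
    # subgenome-specific within-subset third-base preferences (shared across chromosomes)
    inner_h = _box_inner_weights(params.codon_profile_divergence, rng_prof_h)
    inner_l = _box_inner_weights(params.codon_profile_divergence, rng_prof_l)
    inner_mid = [
        {k: (h[k] + l[k]) / 2.0 if h[k].size else h[k] for k in ("gc", "at")}
        for h, l in zip(inner_h, inner_l)
    ]
    inner_eff = {
        SUBGENOME_H: _amplify_inner(inner_mid, inner_h, rho),
        SUBGENOME_L: _amplify_inner(inner_mid, inner_l, rho),
    }

    G, L = params.genes_per_chrom, params.codons_per_gene

    # one-dimensional amino-acid content gradient across chromosome pairs
    gradient_dir = rng_content.normal(size=N_AA)
    gradient_dir /= np.linalg.norm(gradient_dir)
    gradient_pos = rng_content.normal(0.0, params.chrom_content_sd, size=params.n_chrom_pairs)
    aa_dists = []
    shared_probs_c: list[list[np.ndarray]] = []
    div_probs_c: list[dict[str, list[np.ndarray]]] = []
    for c in range(params.n_chrom_pairs):
        p_aa = np.exp(gradient_pos[c] * gradient_dir)
        p_aa /= p_aa.sum()
        aa_dists.append(p_aa)
        # per-chromosome GC3 calibration: Met/Trp share varies with content
        split_h = _gc3_split_probability(params.gc3_h, L, p_aa)
        split_l = _gc3_split_probability(params.gc3_l, L, p_aa)
        split_mid = (split_h + split_l) / 2.0
        split_eff = {
            SUBGENOME_H: split_mid + (split_h - split_mid) / rho,
            SUBGENOME_L: split_mid + (split_l - split_mid) / rho,
        }
        for sub_name, v in split_eff.items():
            if not (0.0 < v < 1.0):
                raise ValueError(
                    "amplified GC3 split outside (0, 1); increase "
                    "divergent_codon_fraction or narrow the gc3 targets"
                )
        shared_probs_c.append(_box_probs(split_mid, inner_mid))
        div_probs_c.append(
            {s: _box_probs(split_eff[s], inner_eff[s]) for s in (SUBGENOME_H, SUBGENOME_L)}
        )

    # crossover events: distinct chromosome pairs while possible
    crossover_chroms = list(
        rng_layout.permutation(params.n_chrom_pairs)[: params.n_crossovers]
    )
    extra = params.n_crossovers - len(crossover_chroms)
    if extra > 0:
        crossover_chroms += list(rng_layout.integers(0, params.n_chrom_pairs, size=extra))
    breakpoints_by_chrom: dict[int, list[int]] = {}
    for c in crossover_chroms:
        bp = int(rng_layout.integers(params.crossover_min_offset,
                                     G - params.crossover_min_offset))
        breakpoints_by_chrom.setdefault(int(c), []).append(bp)

    gene_meta: list[dict] = []  # one entry per gene copy
    pair_meta: list[dict] = []
    truth_sub: dict[str, str] = {}
    truth_bp: dict[str, list[int]] = {}
    truth_bp_slot: dict[str, list[int]] = {}
    chrom_ids: dict[tuple[int, str], str] = {}
    h_phys_side: dict[int, str] = {}

    for c in range(params.n_chrom_pairs):
        pair_name = f"chrpair{c + 1:02d}"
        chrom_ids[(c, "a")] = f"chr{c + 1:02d}a"
        chrom_ids[(c, "b")] = f"chr{c + 1:02d}b"
        h_side = "a" if rng_layout.random() < 0.5 else "b"
        h_phys_side[c] = h_side
        bps = sorted(breakpoints_by_chrom.get(c, []))
        flip_state = np.zeros(G, dtype=bool)
        for bp in bps:
            flip_state[bp:] ^= True

        singleton = rng_layout.random(G) < params.fractionation_rate
        singleton_on_h = rng_layout.random(G) < params.fractionation_bias_h

        pair_series_index = 0
        bp_series: list[int] = []
        bp_iter = iter(bps)
        next_bp = next(bp_iter, None)
        for slot in range(G):
            if next_bp is not None and slot == next_bp:
                bp_series.append(pair_series_index)
                next_bp = next(bp_iter, None)
            # subgenome of the copy sitting on each physical chromosome at this slot
            sub = {}
            for side in ("a", "b"):
                is_h = (side == h_side) ^ bool(flip_state[slot])
                sub[side] = SUBGENOME_H if is_h else SUBGENOME_L
            if singleton[slot]:
                want = SUBGENOME_H if singleton_on_h[slot] else SUBGENOME_L
                side = "a" if sub["a"] == want else "b"
                gid = f"{chrom_ids[(c, side)]}_s{slot:04d}"
                gene_meta.append(
                    {"gene_id": gid, "chrom_key": (c, side), "slot": slot,
                     "subgenome": sub[side], "aa_slot": (c, slot)}
                )
                truth_sub[gid] = sub[side]
            else:
                gids = {}
                for side in ("a", "b"):
                    gid = f"{chrom_ids[(c, side)]}_g{slot:04d}"
                    gids[side] = gid
                    gene_meta.append(
                        {"gene_id": gid, "chrom_key": (c, side), "slot": slot,
                         "subgenome": sub[side], "aa_slot": (c, slot)}
                    )
                    truth_sub[gid] = sub[side]
                pair_meta.append(
                    {"chrom": c, "slot": slot, "gene_a": gids["a"], "gene_b": gids["b"],
                     "series_index": pair_series_index}
                )
                pair_series_index += 1
        truth_bp[pair_name] = bp_series
        truth_bp_slot[pair_name] = bps

    # shared amino-acid sequences: one row per (chromosome, slot)
    aa_rows: dict[tuple[int, int], int] = {}
    for meta in gene_meta:
        aa_rows.setdefault(meta["aa_slot"], len(aa_rows))
    aa_matrix = np.empty((len(aa_rows), L), dtype=np.int16)
    box_matrix = np.empty((len(aa_rows), L), dtype=np.int16)
    shared_mask = rng_mask.random((len(aa_rows), L)) >= rho
    shared_codons = np.empty((len(aa_rows), L), dtype=np.int16)
    rows_by_chrom: dict[int, list[int]] = {}
    for (c, _slot), row in aa_rows.items():
        rows_by_chrom.setdefault(c, []).append(row)
    for c in range(params.n_chrom_pairs):
        rows = np.array(rows_by_chrom[c])
        block = rng_aa.choice(N_AA, size=(len(rows), L), p=aa_dists[c]).astype(np.int16)
        block[:, 0] = _MET
        block[:, -1] = N_AA  # stop family
        aa_matrix[rows] = block
        box_block = _sample_box_matrix(block, rng_aa)
        box_matrix[rows] = box_block
        shared_codons[rows] = _sample_codons_for_boxes(box_block, shared_probs_c[c], rng_codon)

    # per-copy codons: identical to the partner at shared positions,
    # subgenome-specific (amplified GC3 split) at divergent positions
    codon_matrix = np.empty((len(gene_meta), L), dtype=np.int16)
    expected_counts = {SUBGENOME_H: np.zeros(64), SUBGENOME_L: np.zeros(64)}
    for c in range(params.n_chrom_pairs):
        for sub_name in (SUBGENOME_H, SUBGENOME_L):
            idx = [
                i for i, m in enumerate(gene_meta)
                if m["chrom_key"][0] == c and m["subgenome"] == sub_name
            ]
            if not idx:
                continue
            row_ids = np.array([aa_rows[gene_meta[i]["aa_slot"]] for i in idx])
            box_block = box_matrix[row_ids]
            mask = shared_mask[row_ids]
            div = _sample_codons_for_boxes(box_block, div_probs_c[c][sub_name], rng_codon)
            codon_matrix[idx] = np.where(mask, shared_codons[row_ids], div)
            # exact expected codon counts for the realized boxes and masks
            n_shared = np.bincount(box_block[mask], minlength=len(_BOXES))
            n_div = np.bincount(box_block[~mask], minlength=len(_BOXES))
            expected_counts[sub_name] += _expected_counts_for_boxes(
                n_shared, shared_probs_c[c]
            ) + _expected_counts_for_boxes(n_div, div_probs_c[c][sub_name])
    seqs = _codon_rows_to_seqs(codon_matrix)
    cds = {m["gene_id"]: s for m, s in zip(gene_meta, seqs)}

    # coordinates and order per physical chromosome (slot order = 5' -> 3')
    genes: list[GeneRecord] = []
    per_chrom_count: dict[tuple[int, str], int] = {}
    per_chrom_cursor: dict[tuple[int, str], int] = {}
    gene_len = 3 * L
    for meta in gene_meta:
        key = meta["chrom_key"]
        order = per_chrom_count.get(key, 0)
        start = per_chrom_cursor.get(key, 1)
        per_chrom_count[key] = order + 1
        per_chrom_cursor[key] = start + gene_len + 200
        genes.append(
            GeneRecord(
                gene_id=meta["gene_id"],
                chrom_id=chrom_ids[key],
                order_index=order,
                start=start,
                end=start + gene_len - 1,
                strand="+",
                cds=cds[meta["gene_id"]],
            )
        )

    # chromosome X = higher global CDS GC of the two physical copies
    gc_by_chrom: dict[tuple[int, str], tuple[int, int]] = {}
    for meta, seq in zip(gene_meta, seqs):
        gc = seq.count("G") + seq.count("C")
        tot = len(seq)
        old = gc_by_chrom.get(meta["chrom_key"], (0, 0))
        gc_by_chrom[meta["chrom_key"]] = (old[0] + gc, old[1] + tot)

    pairings: list[ChromosomePairing] = []
    pairs: list[HomoeologPair] = []
    x_is_h: dict[str, bool] = {}
    for c in range(params.n_chrom_pairs):
        pair_name = f"chrpair{c + 1:02d}"
        gc_a = gc_by_chrom[(c, "a")][0] / gc_by_chrom[(c, "a")][1]
        gc_b = gc_by_chrom[(c, "b")][0] / gc_by_chrom[(c, "b")][1]
        # deterministic tie-break on chromosome id keeps output stable
        x_side = "a" if (gc_a, chrom_ids[(c, "b")]) >= (gc_b, chrom_ids[(c, "a")]) else "b"
        xp_side = "b" if x_side == "a" else "a"
        pairings.append(
            ChromosomePairing(
                pair_name=pair_name,
                chrom_x=chrom_ids[(c, x_side)],
                chrom_x_prime=chrom_ids[(c, xp_side)],
                global_gc_x=max(gc_a, gc_b),
                global_gc_x_prime=min(gc_a, gc_b),
            )
        )
        x_is_h[pair_name] = (x_side == h_phys_side[c])
        for pm in (m for m in pair_meta if m["chrom"] == c):
            pairs.append(
                HomoeologPair(
                    pair_id=f"{pair_name}_p{pm['slot']:04d}",
                    chrom_pair=pair_name,
                    gene_x=pm["gene_a"] if x_side == "a" else pm["gene_b"],
                    gene_x_prime=pm["gene_b"] if x_side == "a" else pm["gene_a"],
                )
            )

    truth = TruthLabels(
        gene_subgenome=truth_sub,
        breakpoints=truth_bp,
        breakpoints_slot=truth_bp_slot,
        x_is_h=x_is_h,
        codon_profiles={
            s: counts / counts.sum() for s, counts in expected_counts.items()
        },
        gc3_targets={SUBGENOME_H: params.gc3_h, SUBGENOME_L: params.gc3_l},
    )
    return SyntheticGenome(
        params=params, seed=seed, cds=cds, genes=genes,
        pairs=pairs, pairings=pairings, truth=truth,
    )


# ---------------------------------------------------------------------------
# Expression simulation
# ---------------------------------------------------------------------------


@dataclass
class ExpressionTruth:
    """True per-pair, per-timepoint bias used to score downstream calls."""

    table: pd.DataFrame  # pair_id, timepoint, category, direction, silenced, log2fc_true

    @property
    def all_silent_pairs(self) -> set[str]:
        df = self.table
        return set(df.loc[df["category"] == "all_silent", "pair_id"])


def simulate_expression(
    params: SimulationParams,
    genome: SyntheticGenome,
    seed: int,
    noise_sd: float | None = None,
) -> tuple[ExpressionMatrix, ExpressionTruth]:
    """RPKM matrix over the configured timepoints plus bias truth.

    Retained pairs (not all-silent) are biased with probability
    ``bias_fraction``; of these a ``silencing_fraction`` share is realised
    by silencing one copy (RPKM below the expressed threshold).  Biased
    pairs get a |log2 fold change| of 1.5 + Exp(1) toward the designated
    subgenome, consistent across timepoints for a ``consistent_bias_fraction``
    share.  Gaussian noise of sd ``noise_sd`` (log2 scale) is added per
    gene and timepoint; pass 0 for noiseless recovery checks.
    """
    if noise_sd is None:
        noise_sd = params.noise_sd_log2
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    tps = list(params.timepoints)
    thr = params.expressed_threshold
    truth_sub = genome.truth.gene_subgenome

    values: dict[str, np.ndarray] = {}
    rows = []
    for pair in genome.pairs:
        sub_x = truth_sub[pair.gene_x]
        h_gene = pair.gene_x if sub_x == SUBGENOME_H else pair.gene_x_prime
        l_gene = pair.gene_x_prime if sub_x == SUBGENOME_H else pair.gene_x
        u = rng.random()
        if u < params.all_silent_fraction:
            category = "all_silent"
        else:
            v = rng.random()
            if v < params.silencing_fraction:
                category = "silenced"
            elif v < params.bias_fraction:
                category = "biased"
            else:
                category = "neutral"

        base = rng.normal(params.expr_mean_log2, params.expr_sd_log2)
        tau = rng.normal(0.0, params.timepoint_sd_log2, size=len(tps))

        if category == "all_silent":
            h_vals = rng.uniform(0, thr, size=len(tps))
            l_vals = rng.uniform(0, thr, size=len(tps))
            for t, tp in enumerate(tps):
                rows.append((pair.pair_id, tp, category, "not_expressed", False, np.nan))
        elif category == "silenced":
            silent_is_h = rng.random() < 0.5
            expressed = np.maximum(base + tau, 0.5)
            silent = rng.uniform(0, thr, size=len(tps))
            if silent_is_h:
                h_vals, l_vals = silent, 2.0 ** expressed
                direction = "toward_l"
            else:
                h_vals, l_vals = 2.0 ** expressed, silent
                direction = "toward_h"
            for t, tp in enumerate(tps):
                rows.append((pair.pair_id, tp, category, direction, True, np.nan))
        else:
            if category == "biased":
                magnitude = 1.5 + rng.exponential(1.0)
                sign = 1.0 if rng.random() < 0.5 else -1.0
                signs = np.full(len(tps), sign)
                if rng.random() >= params.consistent_bias_fraction and len(tps) > 1:
                    flip_at = rng.integers(0, len(tps))
                    signs[flip_at] *= -1.0
                offsets = signs * magnitude
            else:
                offsets = np.zeros(len(tps))
            centre = np.maximum(base + tau, np.abs(offsets) / 2.0 + 0.1)
            h_log2 = centre + offsets / 2.0
            l_log2 = centre - offsets / 2.0
            if noise_sd > 0:
                h_log2 = h_log2 + rng.normal(0, noise_sd, size=len(tps))
                l_log2 = l_log2 + rng.normal(0, noise_sd, size=len(tps))
            h_vals, l_vals = 2.0 ** h_log2, 2.0 ** l_log2
            for t, tp in enumerate(tps):
                if category == "biased":
                    direction = "toward_h" if offsets[t] > 0 else "toward_l"
                else:
                    direction = "neutral"
                rows.append((pair.pair_id, tp, category, direction, False, offsets[t]))
        values[h_gene] = np.asarray(h_vals, dtype=float)
        values[l_gene] = np.asarray(l_vals, dtype=float)

    # singletons: plain lognormal expression, no pairing truth
    paired_ids = set(values)
    for gene in genome.genes:
        if gene.gene_id in paired_ids:
            continue
        log2 = rng.normal(params.expr_mean_log2, params.expr_sd_log2) + rng.normal(
            0, params.timepoint_sd_log2 + noise_sd, size=len(tps)
        )
        values[gene.gene_id] = 2.0 ** log2

    order = [g.gene_id for g in genome.genes]
    df = pd.DataFrame.from_dict(values, orient="index", columns=tps).loc[order]
    df.index.name = "gene_id"
    truth_df = pd.DataFrame(
        rows, columns=["pair_id", "timepoint", "category", "direction", "silenced", "log2fc_true"]
    )
    return ExpressionMatrix(df), ExpressionTruth(table=truth_df)


def write_expression(
    matrix: ExpressionMatrix, truth: ExpressionTruth, out_dir: str | Path
) -> None:
    out = Path(out_dir)
    write_expression_table(matrix, out / "expression.tsv")
    write_tsv(truth.table, out / "truth_bias.tsv")
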