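"""Per-column divergence scan between two ortholog groups.

Given a pooled multiple sequence alignment whose rows belong to two
functional subfamilies (e.g. DJ-1 orthologs vs HchA orthologs), each
alignment column is scored with the symmetric Kullback-Leibler
divergence between the two groups' amino-acid compositions,

    KL(n) = sum_i p_i log(p_i / q_i) + sum_i q_i log(q_i / p_i)

where p and q are the group A and group B probabilities of amino acid i
at column n. High-scoring columns are candidate specificity-determining
positions: sites whose residue usage separates the subfamilies and which
therefore plausibly underlie their functional differentiation.

Raw column frequencies contain zeros, which make the KL divergence
infinite, so compositions are regularised with an additive pseudocount
(default 0.5 per amino acid, a Jeffreys-style prior). Gaps and unknown
residues (X) are excluded from counts; columns where either group falls
below a minimum occupancy are flagged non-evaluable and left out of the
ranking so that gap-dominated columns cannot top it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import CompositionError, EtraceInputError, GroupingError
from .seqio import AMINO_ACIDS, GAP, UNKNOWN, ColumnMap, GroupedAlignment, column_to_reference_map

AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
N_AA = len(AMINO_ACIDS)


@dataclass
class SiteComposition:
    """Per-group amino-acid composition at one alignment column."""

    column: int  # 1-based
    p: np.ndarray  # group A probabilities over the 20 amino acids
    q: np.ndarray  # group B
    count_a: int  # non-gap, non-X residues in group A
    count_b: int
    occupancy_a: float  # count / group size
    occupancy_b: float
    evaluable: bool = True


@dataclass
class SiteScore:
    column: int  # 1-based alignment column
    kl: float
    ref_a_pos: Optional[int]  # reference residue index or None (gap)
    ref_b_pos: Optional[int]
    modal_a: Optional[str]  # most frequent residue per group
    modal_b: Optional[str]
    conservation_a: Optional[float]  # modal frequency, in [0, 1]
    conservation_b: Optional[float]
    occupancy_a: float
    occupancy_b: float
    evaluable: bool


@dataclass
class DivergenceReport:
    """Ranked divergence scan over every alignment column.

    ``ranked`` holds the evaluable sites by descending KL (ties broken by
    ascending column); ``all_sites`` holds every column in column order.
    """

    ranked: list[SiteScore]
    all_sites: list[SiteScore]
    pseudocount: float
    min_occupancy: float
    log_base: Optional[float]  # None = natural log
    n_a: int
    n_b: int
    ref_a: Optional[str] = None
    ref_b: Optional[str] = None

    @property
    def parameters(self) -> dict:
        return {
            "pseudocount": self.pseudocount,
            "min_occupancy": self.min_occupancy,
            "log_base": self.log_base,
            "n_group_a": self.n_a,
            "n_group_b": self.n_b,
            "ref_a": self.ref_a,
            "ref_b": self.ref_b,
        }


def _column_counts(rows: list[str], column: int) -> np.ndarray:
    """Count the 20 amino acids at a 1-based column; gaps and X excluded."""
    counts = np.zeros(N_AA, dtype=np.int64)
    for r in rows:
        letter = r[column - 1]
        if letter != GAP and letter != UNKNOWN:
            counts[AA_INDEX[letter]] += 1
    return counts


def _group_rows(ga: GroupedAlignment, group: str) -> list[str]:
    return [s.residues for s in ga.members(group)]


def site_composition(
    ga: GroupedAlignment, column: int, pseudocount: float = 0.5
) -> SiteComposition:
    """Pseudocounted amino-acid composition of one column, per group.

    p_i = (count_i + alpha) / (N + 20 alpha) with N the group's non-gap,
    non-X residue count. With alpha = 0 and N = 0 the composition is
    undefined and the site is flagged non-evaluable.
    """
    if pseudocount < 0:
        raise EtraceInputError(f"pseudocount must be >= 0, got {pseudocount}")
    if not 1 <= column <= ga.alignment.length:
        raise IndexError(
            f"column {column} out of range 1..{ga.alignment.length}"
        )
    rows_a, rows_b = _group_rows(ga, "A"), _group_rows(ga, "B")
    ca, cb = _column_counts(rows_a, column), _column_counts(rows_b, column)
    na, nb = int(ca.sum()), int(cb.sum())
    evaluable = True

    def _probs(counts, n):
        nonlocal evaluable
        denom = n + N_AA * pseudocount
        if denom == 0:
            evaluable = False
            return np.full(N_AA, np.nan)
        return (counts + pseudocount) / denom

    return SiteComposition(
        column=column,
        p=_probs(ca, na),
        q=_probs(cb, nb),
        count_a=na,
        count_b=nb,
        occupancy_a=na / len(rows_a),
        occupancy_b=nb / len(rows_b),
        evaluable=evaluable,
    )


def kl_symmetric(p, q, base: Optional[float] = None) -> float:
    """Symmetric Kullback-Leibler divergence between two compositions.

    Natural log by default; ``base`` rescales by 1/ln(base) (the ranking
    is base-invariant). Both vectors must be strictly positive and sum
    to 1 — guaranteed by any positive pseudocount.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != (N_AA,) or q.shape != (N_AA,):
        raise CompositionError(f"compositions must be {N_AA}-vectors")
    if np.any(p <= 0) or np.any(q <= 0):
        raise CompositionError(
            "compositions must be strictly positive; use a pseudocount > 0"
        )
    for name, v in (("p", p), ("q", q)):
        if abs(v.sum() - 1.0) > 1e-6:
            raise CompositionError(f"{name} does not sum to 1 (sum={v.sum():.9f})")
    log_ratio = np.log(p) - np.log(q)
    kl = float(np.dot(p, log_ratio) - np.dot(q, log_ratio))
    if base is not None:
        kl /= math.log(base)
    # clip the tiny negative residue that floating-point cancellation
    # can leave when p == q
    return max(kl, 0.0)


def conservation(
    ga: GroupedAlignment, column: int, group: str
) -> tuple[Optional[str], Optional[float]]:
    """Modal residue of a group at a column and its frequency.

    The frequency denominator is the group's non-gap, non-X count; modal
    ties are broken alphabetically. Returns (None, None) when the column
    is empty for the group.
    """
    if group not in ("A", "B"):
        raise GroupingError(f"group must be 'A' or 'B', got {group!r}")
    counts = _column_counts(_group_rows(ga, group), column)
    total = counts.sum()
    if total == 0:
        return None, None
    best = int(np.argmax(counts))  # argmax takes the first = alphabetical tie-break
    return AMINO_ACIDS[best], float(counts[best] / total)


def conservation_pct(fraction: Optional[float]) -> Optional[int]:
    """Reporting helper: fraction -> nearest-integer percentage."""
    if fraction is None:
        return None
    return round(fraction * 100)


def score_all_sites(
    ga: GroupedAlignment,
    pseudocount: float = 0.5,
    min_occupancy: float = 0.5,
    log_base: Optional[float] = None,
) -> DivergenceReport:
    """Score every alignment column and rank the evaluable ones by KL.

    A column is evaluable when both groups' occupancy (non-gap, non-X
    fraction) reaches ``min_occupancy``. Reference coordinates are
    attached from the grouped alignment's reference sequences when
    present.
    """
    if pseudocount <= 0:
        raise EtraceInputError("score_all_sites requires pseudocount > 0")
    if not 0 <= min_occupancy <= 1:
        raise EtraceInputError("min_occupancy must be in [0, 1]")
    map_a = (
        column_to_reference_map(ga.alignment, ga.ref_a) if ga.ref_a else None
    )
    map_b = (
        column_to_reference_map(ga.alignment, ga.ref_b) if ga.ref_b else None
    )
    # rank on natural-log KL so the ordering is exactly base-invariant;
    # the requested base only rescales the reported values
    scale = 1.0 / math.log(log_base) if log_base is not None else 1.0
    scores: list[SiteScore] = []
    order: dict[int, float] = {}
    for col in range(1, ga.alignment.length + 1):
        comp = site_composition(ga, col, pseudocount)
        evaluable = (
            comp.evaluable
            and comp.occupancy_a >= min_occupancy
            and comp.occupancy_b >= min_occupancy
        )
        kl_nats = kl_symmetric(comp.p, comp.q) if evaluable else math.nan
        order[col] = kl_nats
        kl = kl_nats * scale if evaluable else math.nan
        mod_a, cons_a = conservation(ga, col, "A")
        mod_b, cons_b = conservation(ga, col, "B")
        scores.append(
            SiteScore(
                column=col,
                kl=kl,
                ref_a_pos=map_a.residue_number(col) if map_a else None,
                ref_b_pos=map_b.residue_number(col) if map_b else None,
                modal_a=mod_a,
                modal_b=mod_b,
                conservation_a=cons_a,
                conservation_b=cons_b,
                occupancy_a=comp.occupancy_a,
                occupancy_b=comp.occupancy_b,
                evaluable=evaluable,
            )
        )
    ranked = sorted(
        (s for s in scores if s.evaluable),
        key=lambda s: (-order[s.column], s.column),
    )
    return DivergenceReport(
        ranked=ranked,
        all_sites=scores,
        pseudocount=pseudocount,
        min_occupancy=min_occupancy,
        log_base=log_base,
        n_a=len(ga.members("A")),
        n_b=len(ga.members("B")),
        ref_a=ga.ref_a,
        ref_b=ga.ref_b,
    )


def top_sites(report: DivergenceReport, n: int) -> list[SiteScore]:
    """First min(n, #evaluable) sites of the ranking."""
    if n < 1:
        raise EtraceInputError(f"n must be >= 1, got {n}")
    return report.ranked[:n]


def write_report_tsv(report: DivergenceReport, path) -> None:
    """Write the ranked scan as TSV with a JSON parameter header comment.

    Byte-identical across runs for identical inputs and parameters.
    """
    cols = [
        "rank",
        "column",
        "ref_a_pos",
        "ref_b_pos",
        "modal_a",
        "conservation_a_pct",
        "modal_b",
        "conservation_b_pct",
        "kl",
        "evaluable",
    ]

    def _fmt_pos(p):
        return "gap" if p is None else str(p)

    with open(path, "w") as fh:
        fh.write("# parameters: " + json.dumps(report.parameters, sort_keys=True) + "\n")
        fh.write("\t".join(cols) + "\n")
        rank_of = {s.column: i + 1 for i, s in enumerate(report.ranked)}
        for s in report.all_sites:
            fh.write(
                "\t".join(
                    [
                        str(rank_of.get(s.column, "NA")),
                        str(s.column),
                        _fmt_pos(s.ref_a_pos),
                        _fmt_pos(s.ref_b_pos),
                        s.modal_a or "NA",
                        str(conservation_pct(s.conservation_a) if s.conservation_a is not None else "NA"),
                        s.modal_b or "NA",
                        str(conservation_pct(s.conservation_b) if s.conservation_b is not None else "NA"),
                        f"{s.kl:.10g}" if s.evaluable else "NA",
                        str(s.evaluable),
                    ]
                )
                + "\n"
            )
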