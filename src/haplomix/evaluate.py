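"""Pairwise-consistency accuracy measures for partially assembled haplotypes.

A pair of phased sites (j, j') is *consistent* with the truth when the joint
predicted phase equals the true joint phase or its global switch -- i.e. the
relative phase between the two sites is right.  Counting consistent (CP)
and inconsistent (IP) pairs over all predicted blocks gives

    precision = CP / (CP + IP).

Unlike the switch-error rate, this penalises a switch error in the middle of
a block more than one at its edge, and does not double-charge two adjacent
switch errors (a single flipped site) that leave the flanks mutually
consistent.

The *prediction space* is the set of site pairs inside connected components
(size >= 2) of the co-spanning graph; recall is predicted pairs divided by
the total pairs of that space.  A no-assembly baseline phases each
co-spanned pair by strict majority vote over the fragments spanning both
sites, with tied votes left unpredicted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, TYPE_CHECKING

import numpy as np
import pandas as pd

from .fragments import FragmentSet, PhaseVector
from .scoring import HaplotypeBlock, compute_connectivities, extract_blocks

if TYPE_CHECKING:  # pragma: no cover
    from .vbem import FitResult


@dataclass
class EvalResult:
    """Pairwise accuracy of one prediction against true haplotypes."""

    cp: int
    ip: int
    total_pairs: int
    switch_errors: int = 0
    neighbor_pairs: int = 0

    @property
    def predicted_pairs(self) -> int:
        return self.cp + self.ip

    @property
    def precision(self) -> float:
        n = self.predicted_pairs
        return self.cp / n if n else float("nan")

    @property
    def recall(self) -> float:
        return self.predicted_pairs / self.total_pairs if self.total_pairs else float("nan")

    @property
    def switch_error_rate(self) -> float:
        return self.switch_errors / self.neighbor_pairs if self.neighbor_pairs else float("nan")


def _mismatch_codes(block: HaplotypeBlock, truth: PhaseVector) -> np.ndarray:
    """Per-site XOR of predicted and true phase codes; pairs agree iff equal."""
    out = np.empty(len(block.sites), dtype=np.int64)
    for i, j in enumerate(block.sites):
        j = int(j)
        if j not in truth:
            raise ValueError(f"truth phase missing for site {j}")
        out[i] = block.phases[j] ^ truth[j]
    return out


def pair_consistency(blocks: Sequence[HaplotypeBlock], truth: PhaseVector) -> tuple[int, int]:
    """(CP, IP) summed over all within-block site pairs.

    A pair is consistent iff the predicted relative phase matches the true
    relative phase, so the count is invariant under a global switch of
    either the prediction or the truth.
    """
    cp = ip = 0
    for b in blocks:
        x = _mismatch_codes(b, truth)
        n1 = int(x.sum())
        n0 = len(x) - n1
        cp += n0 * (n0 - 1) // 2 + n1 * (n1 - 1) // 2
        ip += n0 * n1
    return cp, ip


def total_pairs(fs: FragmentSet) -> int:
    """Size of the prediction space: sum of C(|component|, 2)."""
    return sum(len(c) * (len(c) - 1) // 2 for c in fs.connected_components())


def switch_errors(blocks: Sequence[HaplotypeBlock], truth: PhaseVector) -> tuple[int, int]:
    """(switch errors, neighbouring pairs) over consecutive sites in blocks."""
    errs = pairs = 0
    for b in blocks:
        x = _mismatch_codes(b, truth)
        errs += int((x[1:] != x[:-1]).sum())
        pairs += len(x) - 1
    return errs, pairs


def switch_error_rate(blocks: Sequence[HaplotypeBlock], truth: PhaseVector) -> float:
    errs, pairs = switch_errors(blocks, truth)
    return errs / pairs if pairs else float("nan")


def evaluate_blocks(
    fs: FragmentSet, blocks: Sequence[HaplotypeBlock], truth: PhaseVector
) -> EvalResult:
    """Full pairwise evaluation of a block prediction against the truth."""
    cp, ip = pair_consistency(blocks, truth)
    errs, pairs = switch_errors(blocks, truth)
    return EvalResult(
        cp=cp,
        ip=ip,
        total_pairs=total_pairs(fs),
        switch_errors=errs,
        neighbor_pairs=pairs,
    )


def no_assembly_baseline(fs: FragmentSet, truth: PhaseVector) -> EvalResult:
    """Majority-vote phasing of co-spanned pairs, without assembly.

    Every fragment spanning both sites of a pair votes for their relative
    phase (equal or unequal alleles); pairs with a strict majority are
    predicted and scored against the true relative phase, tied pairs are
    left unpredicted.
    """
    votes: dict[tuple[int, int], int] = {}
    counts: dict[tuple[int, int], int] = {}
    for f in fs:
        sites = f.sites
        alleles = f.alleles
        for a in range(len(sites)):
            for b in range(a + 1, len(sites)):
                key = (int(sites[a]), int(sites[b]))
                v = int(alleles[a]) ^ int(alleles[b])  # 1 = alleles differ
                votes[key] = votes.get(key, 0) + (1 if v else -1)
                counts[key] = counts.get(key, 0) + 1
    cp = ip = 0
    for (j1, j2), v in votes.items():
        if v == 0:
            continue  # tie: unpredicted
        pred_rel = 1 if v > 0 else 0
        true_rel = truth[j1] ^ truth[j2]
        if pred_rel == true_rel:
            cp += 1
        else:
            ip += 1
    return EvalResult(cp=cp, ip=ip, total_pairs=total_pairs(fs))


def precision_recall_curve(
    fs: FragmentSet,
    fit: "FitResult",
    truth: PhaseVector,
    thresholds: Sequence[float],
) -> pd.DataFrame:
    """One evaluation row per MC threshold; recall is anti-monotone.

    Connectivities are computed once and reused across thresholds.
    """
    conn = compute_connectivities(fs, getattr(fit, "params", fit))
    tp = total_pairs(fs)
    rows = []
    for t in thresholds:
        blocks = extract_blocks(fs, fit, mc_threshold=t, connectivities=conn)
        res = evaluate_blocks(fs, blocks, truth)
        rows.append(
            (
                t,
                res.cp,
                res.ip,
                res.predicted_pairs,
                tp,
                res.precision,
                res.recall,
                res.switch_error_rate,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "mc_threshold",
            "cp",
            "ip",
            "predicted_pairs",
            "total_pairs",
            "precision",
            "recall",
            "switch_error_rate",
        ],
    )
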