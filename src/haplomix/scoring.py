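"""Connectivity and minimum-connectivity (MC) confidence scores, phase calls
and confident haplotype-block extraction.

The *connectivity* at site j0 is the log-likelihood ratio

    connectivity(j0) = log P(F | Theta) - log P(F | Theta')

where Theta' is Theta *twisted* at j0 (phases flipped for all sites >= j0).
It measures how strongly the data resist exchanging the haplotype labels of
the suffix starting at j0 -- exactly the move that produces a switch error.
Only fragments covering the cut before j0 contribute, so the score is local.

The MC score of a site range (j1, j2) is the minimum connectivity over the
interior cuts j1 < j <= j2.  Confident blocks are maximal runs within a
connected component whose internal cuts all clear an MC threshold (default
6.0 nats); inside such a run every site pair has MC above the threshold.
Scores are reported in nats throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence, TYPE_CHECKING

import numpy as np

from .fragments import FragmentSet, PhaseVector
from .model import LOG_HALF, PhaseParams, _site_logterms, fragment_loglik, twist_params

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from .vbem import FitResult

DEFAULT_MC_THRESHOLD = 6.0
"""Default MC cut for reporting blocks, in nats."""


@dataclass
class HaplotypeBlock:
    """A confidently phased run of sites within one connected component."""

    sites: np.ndarray
    phases: PhaseVector
    boundary_connectivity: dict[int, float]
    """Interior boundary, keyed by the right-hand site, -> connectivity."""
    mc: float

    def __post_init__(self) -> None:
        self.sites = np.asarray(self.sites, dtype=np.int64)
        if len(self.sites) < 2:
            raise ValueError("a block needs at least two sites")
        if self.boundary_connectivity:
            expect = min(self.boundary_connectivity.values())
            if not np.isclose(self.mc, expect):
                raise ValueError("mc must equal the minimum boundary connectivity")

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def start(self) -> int:
        return int(self.sites[0])

    @property
    def end(self) -> int:
        return int(self.sites[-1])


def connectivity(fs: FragmentSet, params: PhaseParams, j0: int) -> float:
    """Log-likelihood drop from twisting the parameters at site j0.

    Computed as the restricted sum over fragments covering the cut before
    j0 (the contribution of every other fragment cancels); 0.0 when no
    fragment covers the cut.
    """
    if not 1 <= j0 <= fs.num_sites:
        raise ValueError(f"j0={j0} outside 1..{fs.num_sites}")
    twisted = twist_params(params, j0)
    total = 0.0
    for f in fs.covering_fragments(j0):
        total += fragment_loglik(f, params) - fragment_loglik(f, twisted)
    return total


def compute_connectivities(fs: FragmentSet, params: PhaseParams) -> np.ndarray:
    """Connectivity at every site, shape (M,); entry j-1 is connectivity(j).

    Vectorised: for a fragment with per-site, per-haplotype log factors
    a[k, h], twisting at a cut between spanned positions t and t+1 swaps
    the haplotype role of the suffix, so the twisted log-likelihood is
    logsumexp_h(log 0.5 + A_h(t) + S_{1-h} - A_{1-h}(t)) with A the
    within-fragment prefix sums and S the totals.  The drop is accumulated
    onto every cut between the two spanned positions via a difference
    array.
    """
    m = fs.num_sites
    conn = np.zeros(m)
    offsets, sites0, alleles, frag_index = fs._flat
    if len(sites0) == 0:
        return conn
    a = _site_logterms(sites0, alleles, params)  # (K, 2)
    c = np.cumsum(a, axis=0)
    seg_base = np.concatenate(([[0.0, 0.0]], c[offsets[1:-1] - 1]), axis=0)  # (N, 2)
    prefix = c - seg_base[frag_index]  # inclusive within-fragment prefix sums
    totals = prefix[offsets[1:] - 1]  # (N, 2)
    ll_full = np.logaddexp(LOG_HALF + totals[:, 0], LOG_HALF + totals[:, 1])

    # interior positions: k such that k+1 belongs to the same fragment
    interior = np.ones(len(sites0), dtype=bool)
    interior[offsets[1:] - 1] = False
    k = np.nonzero(interior)[0]
    fi = frag_index[k]
    a0, a1 = prefix[k, 0], prefix[k, 1]
    s0, s1 = totals[fi, 0], totals[fi, 1]
    ll_cut = np.logaddexp(LOG_HALF + a0 + (s1 - a1), LOG_HALF + a1 + (s0 - a0))
    drop = ll_full[fi] - ll_cut

    # the drop applies to every cut j with sites[k] < j <= sites[k+1] (1-based)
    left = sites0[k] + 1  # 0-based index of cut j = sites[k] + 1
    right = sites0[k + 1] + 1  # one past the 0-based index of cut j = sites[k+1]
    diff = np.zeros(m + 1)
    np.add.at(diff, left, drop)
    np.add.at(diff, right, -drop)
    conn = np.cumsum(diff)[:m]
    return conn


def mc_score(connectivities: np.ndarray | Mapping[int, float], j1: int, j2: int) -> float:
    """Minimum connectivity over the cuts j1 < j <= j2."""
    if j1 >= j2:
        raise ValueError("mc_score requires j1 < j2")
    if isinstance(connectivities, Mapping):
        return min(connectivities[j] for j in range(j1 + 1, j2 + 1))
    arr = np.asarray(connectivities, dtype=np.float64)
    return float(arr[j1 : j2].min())


def call_phases(fit: "FitResult | PhaseParams") -> PhaseVector:
    """Most probable phase per site from the posterior-mean parameters.

    Exact ties are broken deterministically to phase (0, 1).
    """
    params = getattr(fit, "params", fit)
    codes = (params.theta[:, 1] > params.theta[:, 0]).astype(np.int64)
    return PhaseVector.from_codes(codes)


def extract_blocks(
    fs: FragmentSet,
    fit: "FitResult | PhaseParams",
    mc_threshold: float = DEFAULT_MC_THRESHOLD,
    connectivities: np.ndarray | None = None,
) -> list[HaplotypeBlock]:
    """Confident blocks: runs of component sites whose cuts clear the threshold.

    Within each connected component (consecutive in component order, not in
    raw coordinates) the boundary between adjacent member sites s, s' is
    scored by the minimum connectivity over the cuts s < j <= s'; maximal
    runs whose boundaries all reach ``mc_threshold`` become blocks, and runs
    of fewer than two sites are discarded.  Every site pair inside a block
    therefore has MC >= ``mc_threshold``.
    """
    params = getattr(fit, "params", fit)
    if connectivities is None:
        connectivities = compute_connectivities(fs, params)
    phases = call_phases(params)
    blocks: list[HaplotypeBlock] = []
    for comp in fs.connected_components():
        runs: list[list[int]] = [[int(comp[0])]]
        bounds: list[dict[int, float]] = [{}]
        for prev, cur in zip(comp[:-1], comp[1:]):
            b = mc_score(connectivities, int(prev), int(cur))
            if b >= mc_threshold:
                runs[-1].append(int(cur))
                bounds[-1][int(cur)] = float(b)
            else:
                runs.append([int(cur)])
                bounds.append({})
        for sites, bc in zip(runs, bounds):
            if len(sites) < 2:
                continue
            blocks.append(
                HaplotypeBlock(
                    sites=np.asarray(sites),
                    phases=phases.restrict(sites),
                    boundary_connectivity=bc,
                    mc=min(bc.values()),
                )
            )
    return blocks


# ---------------------------------------------------------------------------
# Block file I/O
# ---------------------------------------------------------------------------
#
# Header line per block:  BLOCK start=<j1> end=<j2> n=<k> MC=<score>
# followed by per-site lines  <site> <hap0_allele> <hap1_allele> <conn|.>
# where the fourth column is the connectivity at the site's left boundary
# ('.' for the first site of the block).  Scores are in nats.


def write_blocks(blocks: Sequence[HaplotypeBlock], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# haplotype blocks; MC and connectivities in nats\n")
        for b in blocks:
            fh.write(f"BLOCK start={b.start} end={b.end} n={len(b)} MC={b.mc:.6g}\n")
            for j in b.sites:
                j = int(j)
                h0 = b.phases.hap_allele(j, 0)
                h1 = b.phases.hap_allele(j, 1)
                conn = b.boundary_connectivity.get(j)
                conn_s = "." if conn is None else f"{conn:.6g}"
                fh.write(f"{j} {h0} {h1} {conn_s}\n")


def read_blocks(path: str | Path) -> list[HaplotypeBlock]:
    blocks: list[HaplotypeBlock] = []
    sites: list[int] = []
    codes: dict[int, int] = {}
    bc: dict[int, float] = {}

    def flush() -> None:
        if sites:
            blocks.append(
                HaplotypeBlock(
                    sites=np.asarray(sites),
                    phases=PhaseVector({j: codes[j] for j in sites}),
                    boundary_connectivity=dict(bc),
                    mc=min(bc.values()) if bc else float("inf"),
                )
            )

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("BLOCK"):
                flush()
                sites, bc = [], {}
                continue
            toks = line.split()
            j, h0 = int(toks[0]), int(toks[1])
            sites.append(j)
            codes[j] = h0  # phase code equals the hap-0 allele
            if toks[3] != ".":
                bc[j] = float(toks[3])
    flush()
    return blocks
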