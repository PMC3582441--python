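"""SNP fragment data model and text I/O for single-individual haplotyping.

A *SNP fragment* is the projection of one sequenced DNA fragment (or merged
read cluster) onto the heterozygous sites of a diploid genome: a sparse map
from 1-based site index to a binary allele.  Alleles are recoded to {0, 1}
per site, so the two haplotypes are described by a *phase vector* assigning
each site one of the two phases (0, 1) or (1, 0) -- which allele sits on
haplotype 0 and which on haplotype 1.  Because the labelling of the two
haplotypes is arbitrary, a phase vector and its site-wise complement are
equivalent predictions.

A fragment *spans* a site if it reports an allele there; it *covers* site j
if it spans sites on both sides of the cut between j-1 and j (possibly
non-consecutively).  Fragments spanning fewer than two heterozygous sites
carry no phase information and are dropped on load.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components as _cc

log = logging.getLogger(__name__)

PHASES: tuple[tuple[int, int], tuple[int, int]] = ((0, 1), (1, 0))
"""The two possible phases at a heterozygous site; index 0 is (0, 1)."""


class FragmentParseError(ValueError):
    """Raised when a fragment or truth file cannot be parsed."""


@dataclass
class SNPFragment:
    """One sequenced fragment as a sparse site -> allele map.

    Parameters
    ----------
    fragment_id:
        Free-form identifier (must contain no whitespace for round-trip I/O).
    sites:
        1-based heterozygous-site indices, strictly increasing after
        normalisation.
    alleles:
        Binary alleles, aligned with ``sites``.
    """

    fragment_id: str
    sites: np.ndarray
    alleles: np.ndarray

    def __post_init__(self) -> None:
        self.sites = np.asarray(self.sites, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.sites.ndim != 1 or self.sites.shape != self.alleles.shape:
            raise ValueError("sites and alleles must be 1-D arrays of equal length")
        order = np.argsort(self.sites, kind="stable")
        self.sites = self.sites[order]
        self.alleles = self.alleles[order]
        if len(self.sites) and self.sites[0] < 1:
            raise ValueError(f"fragment {self.fragment_id!r}: site indices must be >= 1")
        if np.any(np.diff(self.sites) == 0):
            raise ValueError(f"fragment {self.fragment_id!r}: duplicate site index")
        if np.any((self.alleles != 0) & (self.alleles != 1)):
            raise ValueError(f"fragment {self.fragment_id!r}: alleles must be 0 or 1")

    @classmethod
    def from_dict(cls, fragment_id: str, alleles: Mapping[int, int]) -> "SNPFragment":
        sites = np.fromiter(alleles.keys(), dtype=np.int64, count=len(alleles))
        vals = np.fromiter(alleles.values(), dtype=np.int8, count=len(alleles))
        return cls(fragment_id, sites, vals)

    def to_dict(self) -> dict[int, int]:
        return {int(j): int(a) for j, a in zip(self.sites, self.alleles)}

    def __len__(self) -> int:
        return len(self.sites)

    def allele_at(self, j: int) -> int:
        idx = np.searchsorted(self.sites, j)
        if idx >= len(self.sites) or self.sites[idx] != j:
            raise KeyError(f"fragment {self.fragment_id!r} does not span site {j}")
        return int(self.alleles[idx])

    def spans(self, j: int) -> bool:
        idx = np.searchsorted(self.sites, j)
        return idx < len(self.sites) and self.sites[idx] == j

    def covers(self, j: int) -> bool:
        """True iff some spanned pair j1 < j <= j2 brackets the cut before j."""
        if len(self.sites) < 2:
            return False
        return bool(self.sites[0] < j <= self.sites[-1])


@dataclass
class PhaseVector:
    """Per-site phase assignment, possibly partial.

    ``codes[j]`` is 0 for phase (0, 1) -- allele 0 on haplotype 0 -- and 1
    for phase (1, 0).  The site-wise complement (:meth:`switched`) is an
    equivalent prediction, and all comparison code in this package treats
    the two identically.
    """

    codes: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.codes = {int(j): int(c) for j, c in self.codes.items()}
        for j, c in self.codes.items():
            if j < 1:
                raise ValueError("site indices must be >= 1")
            if c not in (0, 1):
                raise ValueError("phase codes must be 0 or 1")

    def __getitem__(self, j: int) -> int:
        return self.codes[j]

    def __contains__(self, j: int) -> bool:
        return j in self.codes

    def __len__(self) -> int:
        return len(self.codes)

    def sites(self) -> list[int]:
        return sorted(self.codes)

    def phase_at(self, j: int) -> tuple[int, int]:
        return PHASES[self.codes[j]]

    def hap_allele(self, j: int, h: int) -> int:
        """Allele carried by haplotype ``h`` at site ``j``."""
        return self.codes[j] ^ h

    def switched(self) -> "PhaseVector":
        """The equivalent prediction with haplotype labels exchanged."""
        return PhaseVector({j: 1 - c for j, c in self.codes.items()})

    def restrict(self, sites: Iterable[int]) -> "PhaseVector":
        return PhaseVector({j: self.codes[j] for j in sites})

    @classmethod
    def from_codes(cls, codes: Sequence[int], sites: Sequence[int] | None = None) -> "PhaseVector":
        """Build from an array of codes; sites default to 1..len(codes)."""
        if sites is None:
            sites = range(1, len(codes) + 1)
        return cls(dict(zip(sites, (int(c) for c in codes))))


class FragmentSet:
    """A collection of SNP fragments over sites 1..M with derived indexes.

    Fragments spanning fewer than two sites are dropped at construction and
    counted in :attr:`n_dropped`.  ``num_sites`` (M) defaults to the largest
    spanned index and may be supplied explicitly, e.g. when truth covers
    sites no fragment reaches.
    """

    def __init__(
        self,
        fragments: Iterable[SNPFragment],
        num_sites: int | None = None,
        n_dropped: int = 0,
    ) -> None:
        kept: list[SNPFragment] = []
        for f in fragments:
            if len(f) < 2:
                n_dropped += 1
            else:
                kept.append(f)
        self.fragments: list[SNPFragment] = kept
        self.n_dropped = n_dropped
        max_site = max((int(f.sites[-1]) for f in kept), default=0)
        if num_sites is None:
            num_sites = max_site
        elif num_sites < max_site:
            raise ValueError(f"num_sites={num_sites} < largest spanned index {max_site}")
        self.num_sites = int(num_sites)
        if n_dropped:
            log.info("dropped %d fragment(s) spanning <2 sites", n_dropped)

    # -- basic container protocol ------------------------------------------

    def __len__(self) -> int:
        return len(self.fragments)

    def __iter__(self) -> Iterator[SNPFragment]:
        return iter(self.fragments)

    def __getitem__(self, i: int) -> SNPFragment:
        return self.fragments[i]

    @property
    def num_fragments(self) -> int:
        return len(self.fragments)

    # -- flat (CSR-like) layout used by the numerical modules --------------

    @cached_property
    def _flat(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(offsets, sites0, alleles, frag_index) concatenated over fragments.

        ``offsets`` has length N+1; entries of fragment i occupy the slice
        ``offsets[i]:offsets[i+1]``.  ``sites0`` is 0-based.
        """
        lengths = np.fromiter((len(f) for f in self.fragments), dtype=np.int64,
                              count=len(self.fragments))
        offsets = np.concatenate(([0], np.cumsum(lengths)))
        if len(self.fragments):
            sites0 = np.concatenate([f.sites for f in self.fragments]) - 1
            alleles = np.concatenate([f.alleles for f in self.fragments]).astype(np.int64)
        else:
            sites0 = np.zeros(0, dtype=np.int64)
            alleles = np.zeros(0, dtype=np.int64)
        frag_index = np.repeat(np.arange(len(self.fragments)), lengths)
        return offsets, sites0, alleles, frag_index

    # -- spanning / covering indexes ---------------------------------------

    @cached_property
    def span_index(self) -> dict[int, list[SNPFragment]]:
        idx: dict[int, list[SNPFragment]] = {}
        for f in self.fragments:
            for j in f.sites:
                idx.setdefault(int(j), []).append(f)
        return idx

    @cached_property
    def cover_index(self) -> dict[int, list[SNPFragment]]:
        idx: dict[int, list[SNPFragment]] = {}
        for f in self.fragments:
            for j in range(int(f.sites[0]) + 1, int(f.sites[-1]) + 1):
                idx.setdefault(j, []).append(f)
        return idx

    def spanning_fragments(self, j: int) -> list[SNPFragment]:
        self._check_site(j)
        return self.span_index.get(j, [])

    def covering_fragments(self, j: int) -> list[SNPFragment]:
        """Fragments with spanned sites j1 < j <= j2 on both sides of the cut."""
        self._check_site(j)
        return self.cover_index.get(j, [])

    def _check_site(self, j: int) -> None:
        if not 1 <= j <= self.num_sites:
            raise ValueError(f"site {j} outside 1..{self.num_sites}")

    # -- connected components ----------------------------------------------

    def connected_components(self) -> list[np.ndarray]:
        """Site clusters joined by co-spanning fragments.

        Nodes are sites; an edge joins two sites co-spanned by at least one
        fragment.  Components of size 1 are discarded.  Components may be
        non-contiguous in site coordinates.  Returned as sorted arrays of
        1-based sites, ordered by their smallest member.
        """
        if not self.fragments:
            return []
        # Chaining consecutive spanned sites within each fragment yields the
        # same components as the full co-spanning clique.
        rows = np.concatenate([f.sites[:-1] for f in self.fragments]) - 1
        cols = np.concatenate([f.sites[1:] for f in self.fragments]) - 1
        m = self.num_sites
        graph = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(m, m))
        n_comp, labels = _cc(graph, directed=False)
        spanned = np.zeros(m, dtype=bool)
        _, sites0, _, _ = self._flat
        spanned[sites0] = True
        comps: dict[int, list[int]] = {}
        for j0 in np.nonzero(spanned)[0]:
            comps.setdefault(labels[j0], []).append(int(j0) + 1)
        out = [np.asarray(c, dtype=np.int64) for c in comps.values() if len(c) >= 2]
        out.sort(key=lambda c: int(c[0]))
        return out


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------
#
# Two text dialects are supported.
#
# ``hapcut``: one fragment per line,
#     <n_blocks> <id> <start_1> <alleles_1> ... <start_n> <alleles_n> [qual]
# where each block is a run of consecutive spanned sites starting at the
# 1-based index <start_k> with one 0/1 character per site.  A single optional
# trailing token is accepted as a quality string and ignored.
#
# ``matrix``: one fragment per row of characters over {0, 1, -}; column k
# (1-based) is site k and '-' marks an unspanned site.


def _parse_hapcut_line(line: str, lineno: int) -> SNPFragment:
    toks = line.split()
    try:
        n_blocks = int(toks[0])
    except (ValueError, IndexError):
        raise FragmentParseError(f"line {lineno}: expected leading block count") from None
    if n_blocks < 1 or len(toks) < 2 + 2 * n_blocks:
        raise FragmentParseError(f"line {lineno}: truncated record")
    if len(toks) > 2 + 2 * n_blocks + 1:
        raise FragmentParseError(f"line {lineno}: too many fields for {n_blocks} block(s)")
    frag_id = toks[1]
    sites: list[int] = []
    alleles: list[int] = []
    seen: set[int] = set()
    for b in range(n_blocks):
        try:
            start = int(toks[2 + 2 * b])
        except ValueError:
            raise FragmentParseError(f"line {lineno}: bad block start {toks[2 + 2 * b]!r}") from None
        allele_str = toks[3 + 2 * b]
        for k, ch in enumerate(allele_str):
            if ch not in "01":
                raise FragmentParseError(f"line {lineno}: allele character {ch!r} not in {{0,1}}")
            j = start + k
            if j in seen:
                raise FragmentParseError(f"line {lineno}: duplicate site {j}")
            seen.add(j)
            sites.append(j)
            alleles.append(int(ch))
    return SNPFragment(frag_id, np.array(sites), np.array(alleles))


def _parse_matrix_line(line: str, lineno: int) -> SNPFragment:
    row = line.strip()
    sites: list[int] = []
    alleles: list[int] = []
    for k, ch in enumerate(row):
        if ch == "-":
            continue
        if ch not in "01":
            raise FragmentParseError(f"line {lineno}: allele character {ch!r} not in {{0,1,-}}")
        sites.append(k + 1)
        alleles.append(int(ch))
    return SNPFragment(f"row{lineno}", np.array(sites), np.array(alleles))


def read_fragments(
    path: str | Path,
    dialect: str = "hapcut",
    num_sites: int | None = None,
) -> FragmentSet:
    """Load a fragment file; fragments spanning <2 sites are dropped and counted."""
    if dialect not in ("hapcut", "matrix"):
        raise ValueError(f"unknown dialect {dialect!r}")
    frags: list[SNPFragment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if dialect == "hapcut":
                frags.append(_parse_hapcut_line(line, lineno))
            else:
                frags.append(_parse_matrix_line(line, lineno))
    fs = FragmentSet(frags, num_sites=num_sites)
    log.info("read %d fragments (%d dropped) from %s", len(fs), fs.n_dropped, path)
    return fs


def write_fragments(fs: FragmentSet, path: str | Path, dialect: str = "hapcut") -> None:
    """Write fragments; mirrors :func:`read_fragments` for round-trips."""
    with open(path, "w") as fh:
        for f in fs:
            if dialect == "hapcut":
                # split into runs of consecutive sites
                breaks = np.nonzero(np.diff(f.sites) > 1)[0] + 1
                starts = np.concatenate(([0], breaks))
                ends = np.concatenate((breaks, [len(f.sites)]))
                parts = []
                for s, e in zip(starts, ends):
                    parts.append(str(int(f.sites[s])))
                    parts.append("".join(str(int(a)) for a in f.alleles[s:e]))
                fh.write(f"{len(starts)} {f.fragment_id} {' '.join(parts)}\n")
            elif dialect == "matrix":
                row = np.full(fs.num_sites, "-", dtype="U1")
                row[f.sites - 1] = [str(int(a)) for a in f.alleles]
                fh.write("".join(row) + "\n")
            else:
                raise ValueError(f"unknown dialect {dialect!r}")


def read_truth(path: str | Path) -> PhaseVector:
    """Read a true-phase file: lines ``<site_index> <allele_of_hap0>``."""
    codes: dict[int, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            toks = line.split()
            if len(toks) != 2:
                raise FragmentParseError(f"line {lineno}: expected '<site> <allele>'")
            try:
                j, a = int(toks[0]), int(toks[1])
            except ValueError:
                raise FragmentParseError(f"line {lineno}: non-integer field") from None
            if a not in (0, 1):
                raise FragmentParseError(f"line {lineno}: allele must be 0 or 1")
            if j in codes:
                raise FragmentParseError(f"line {lineno}: duplicate site {j}")
            codes[j] = a
    return PhaseVector(codes)


def write_truth(truth: PhaseVector, path: str | Path) -> None:
    with open(path, "w") as fh:
        for j in truth.sites():
            fh.write(f"{j} {truth[j]}\n")
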