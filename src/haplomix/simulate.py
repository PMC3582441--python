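"""Synthetic fragment datasets for exercising the assembler.

The generator follows the classic haplotype-assembly benchmarking recipe:
draw M random heterozygous phases, replicate each of the two haplotypes c
times, cut every copy into consecutive pieces of length uniform in
[l1, l2], and flip each emitted allele independently with probability e.
Defaults (M=1000, c=5, l1=3, l2=7, e=0.1) emulate short multi-SNP
fragments at ~10x site coverage with a 10% per-allele error rate.  The
final remainder of a copy may be shorter than l1; remainders of fewer than
two sites are dropped (they carry no phase information), which keeps
coverage uniform otherwise.

Chimeras -- fragments whose suffix switches to the other haplotype, as
produced by erroneous merging of read clusters in pooled long-fragment
sequencing -- can be injected at a given rate for studying the chimerity
filter.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .fragments import FragmentSet, PhaseVector, SNPFragment

log = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """Parameters of the fragment generator.

    num_sites:
        M, number of heterozygous sites.
    coverage:
        c, copies of each haplotype cut into fragments (site coverage 2c).
    min_len / max_len:
        l1, l2 fragment-length bounds in sites; 2 <= l1 <= l2.
    error_rate:
        e, independent per-allele flip probability, in [0, 0.5).
    chimera_rate:
        fraction of fragments whose suffix is resampled from the opposite
        haplotype.
    """

    num_sites: int = 1000
    coverage: int = 5
    min_len: int = 3
    max_len: int = 7
    error_rate: float = 0.1
    chimera_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_len < 2:
            raise ValueError("min_len must be >= 2")
        if self.max_len < self.min_len:
            raise ValueError("max_len must be >= min_len")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must lie in [0, 0.5)")
        if not 0.0 <= self.chimera_rate <= 1.0:
            raise ValueError("chimera_rate must lie in [0, 1]")
        if self.num_sites < 2 or self.coverage < 1:
            raise ValueError("need num_sites >= 2 and coverage >= 1")


def simulate_dataset(config: SimulationConfig) -> tuple[FragmentSet, PhaseVector]:
    """Generate (fragments, truth); bit-identical for identical config.

    If ``config.chimera_rate`` > 0, chimeras are injected afterwards via
    :func:`inject_chimeras` (labels are regenerated there when needed).
    """
    rng = np.random.default_rng(config.seed)
    m = config.num_sites
    codes = rng.integers(0, 2, size=m)
    truth = PhaseVector.from_codes(codes)
    frags: list[SNPFragment] = []
    n_short = 0
    for h in (0, 1):
        hap = codes ^ h  # allele of haplotype h at sites 1..M
        for rep in range(config.coverage):
            pos = 0
            piece = 0
            while pos < m:
                length = int(rng.integers(config.min_len, config.max_len + 1))
                end = min(pos + length, m)
                sites = np.arange(pos + 1, end + 1)
                alleles = hap[pos:end].copy()
                flips = rng.random(end - pos) < config.error_rate
                alleles ^= flips.astype(np.int64)
                if end - pos >= 2:
                    frags.append(
                        SNPFragment(f"h{h}r{rep}p{piece}", sites, alleles)
                    )
                else:
                    n_short += 1
                pos = end
                piece += 1
    fs = FragmentSet(frags, num_sites=m, n_dropped=n_short)
    if config.chimera_rate > 0:
        fs, _ = inject_chimeras(
            fs,
            truth,
            rate=config.chimera_rate,
            error_rate=config.error_rate,
            seed=int(rng.integers(2**31)),
        )
    return fs, truth


def _infer_origin(f: SNPFragment, truth: PhaseVector) -> int:
    """Best-matching haplotype of a fragment (ties to 0)."""
    codes = np.array([truth[int(j)] for j in f.sites], dtype=np.int64)
    match0 = int((f.alleles == codes).sum())  # haplotype 0 carries allele = code
    return 0 if 2 * match0 >= len(f) else 1


def inject_chimeras(
    fs: FragmentSet,
    truth: PhaseVector,
    rate: float,
    error_rate: float = 0.1,
    seed: int = 0,
) -> tuple[FragmentSet, np.ndarray]:
    """Replace a Bernoulli(rate) subset of fragments with chimeras.

    For each selected fragment a split position is drawn uniformly among
    the spanned sites excluding the last; alleles after the split are
    resampled from the *opposite* haplotype (relative to the fragment's
    inferred origin) and re-exposed to flips at ``error_rate``.  Returns
    the new set and a boolean label array aligned with the fragments.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out: list[SNPFragment] = []
    labels = np.zeros(len(fs), dtype=bool)
    for i, f in enumerate(fs):
        if rng.random() >= rate:
            out.append(f)
            continue
        labels[i] = True
        h = _infer_origin(f, truth)
        t = int(rng.integers(0, len(f) - 1))  # split after spanned position t
        codes = np.array([truth[int(j)] for j in f.sites], dtype=np.int64)
        alleles = f.alleles.astype(np.int64).copy()
        suffix = codes[t + 1 :] ^ (1 - h)
        flips = rng.random(len(suffix)) < error_rate
        alleles[t + 1 :] = suffix ^ flips.astype(np.int64)
        out.append(SNPFragment(f.fragment_id + "_chim", f.sites.copy(), alleles))
    n = int(labels.sum())
    if n:
        log.info("inject_chimeras: converted %d/%d fragment(s)", n, len(fs))
    return FragmentSet(out, num_sites=fs.num_sites), labels
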