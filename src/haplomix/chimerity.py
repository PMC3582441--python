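"""Detection of chimeric fragments against known haplotypes.

In pooled long-fragment protocols, read clusters from homologous regions of
the *two* chromosomes are occasionally merged into a single SNP fragment.
Such a chimera matches one haplotype on a prefix and the other haplotype on
the suffix, and it actively misleads haplotype assembly.

Given true haplotypes, a fragment f is scored by the log-likelihood gain
from breaking it in two:

    chimerity(f) = max_{j, h} [ log P0(f_<=j | h) + log P0(f_>j | h-bar) ]
                   - max_h log P0(f | h)

with P0(f | h) = (1 - alpha0)^n(f,h) * alpha0^(|X(f)| - n(f,h)), where
n(f, h) counts sites where f matches haplotype h and alpha0 is the empirical
per-allele error rate (default 0.028).  The split index j runs over the
spanned sites excluding the last, so both parts are non-empty; allowing the
degenerate split would pin every fragment at chimerity 0.  Scores are in
nats: a clean fragment of any length scores log(alpha0 / (1 - alpha0))
(~ -3.55 at the default alpha0) and a perfect half-and-half chimera scores
~ +3.55 per site of its shorter half.  Fragments above a threshold
(default 10) are removed.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .fragments import FragmentSet, PhaseVector, SNPFragment

log = logging.getLogger(__name__)

DEFAULT_ALPHA0 = 0.028
"""Empirical per-allele error rate used in the chimerity likelihood."""

DEFAULT_CHIMERITY_THRESHOLD = 10.0
"""Fragments scoring above this (in nats) are treated as chimeric."""


def _truth_codes(f: SNPFragment, truth: PhaseVector) -> np.ndarray:
    try:
        return np.array([truth[int(j)] for j in f.sites], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(
            f"truth phase missing for site {exc.args[0]} spanned by {f.fragment_id!r}"
        ) from None


def truth_loglik(
    f: SNPFragment, truth: PhaseVector, h: int, alpha0: float = DEFAULT_ALPHA0
) -> float:
    """log P0(f | h): binomial-error likelihood of f against haplotype h."""
    if h not in (0, 1):
        raise ValueError("h must be 0 or 1")
    codes = _truth_codes(f, truth)
    hap = codes ^ h  # allele of haplotype h at each spanned site
    n_match = int((f.alleles == hap).sum())
    n_total = len(f)
    return n_match * np.log1p(-alpha0) + (n_total - n_match) * np.log(alpha0)


def chimerity(
    f: SNPFragment, truth: PhaseVector, alpha0: float = DEFAULT_ALPHA0
) -> tuple[float, int]:
    """Chimerity score and the best split site (last site of the prefix).

    Requires |X(f)| >= 2; the split leaves both parts non-empty.
    """
    if len(f) < 2:
        raise ValueError("chimerity is undefined for fragments spanning <2 sites")
    codes = _truth_codes(f, truth)
    la, l1a = np.log(alpha0), np.log1p(-alpha0)
    # match[k, h]: does the fragment match haplotype h at spanned position k?
    best_unsplit = -np.inf
    best_split = -np.inf
    best_site = int(f.sites[0])
    lengths = np.arange(1, len(f) + 1)
    for h in (0, 1):
        match = (f.alleles == (codes ^ h)).astype(np.int64)
        cum = np.cumsum(match)
        total = int(cum[-1])
        best_unsplit = max(best_unsplit, total * l1a + (len(f) - total) * la)
        # prefix against h, suffix against h-bar; split after position t
        pre = cum[:-1]
        pre_len = lengths[:-1]
        suf = (len(f) - total) - (pre_len - pre)  # suffix mismatches vs h = matches vs h-bar
        suf_len = len(f) - pre_len
        score = pre * l1a + (pre_len - pre) * la + suf * l1a + (suf_len - suf) * la
        t = int(np.argmax(score))
        if score[t] > best_split:
            best_split = float(score[t])
            best_site = int(f.sites[t])
    return float(best_split - best_unsplit), best_site


def chimerity_report(
    fs: FragmentSet,
    truth: PhaseVector,
    alpha0: float = DEFAULT_ALPHA0,
    threshold: float = DEFAULT_CHIMERITY_THRESHOLD,
) -> pd.DataFrame:
    """Per-fragment chimerity table with the removal flag at ``threshold``."""
    rows = []
    for f in fs:
        score, split = chimerity(f, truth, alpha0)
        rows.append((f.fragment_id, len(f), score, split, score > threshold))
    return pd.DataFrame(
        rows, columns=["fragment_id", "n_sites", "chimerity", "best_split_site", "removed"]
    )


def filter_chimeric(
    fs: FragmentSet,
    truth: PhaseVector,
    threshold: float = DEFAULT_CHIMERITY_THRESHOLD,
    alpha0: float = DEFAULT_ALPHA0,
) -> FragmentSet:
    """Fragments with chimerity <= ``threshold``; the removal count is logged."""
    kept = [f for f in fs if chimerity(f, truth, alpha0)[0] <= threshold]
    removed = len(fs) - len(kept)
    log.info(
        "filter_chimeric: removed %d/%d fragment(s) at threshold %g", removed, len(fs), threshold
    )
    return FragmentSet(kept, num_sites=fs.num_sites)
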