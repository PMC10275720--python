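"""Shared statistical primitives: one-sample t, Pearson r, Fisher Z, and the
seeded permutation engine used by both the sweetspot and network validations.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

#: Signed sentinel magnitude returned for a degenerate one-sample t
#: (zero sample variance around a nonzero mean).
DEGENERATE_T = 1e6


def one_sample_t(values, return_flag: bool = False):
    """One-sample t statistic of ``values`` against a zero population mean.

    t = mean / (sd / sqrt(n)) with the (n-1)-denominator sample sd. A zero-sd
    sample yields t = 0 when the mean is zero, otherwise a signed sentinel of
    magnitude 1e6 with a degenerate flag.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D sample of length >= 2")
    mean = x.mean()
    sd = x.std(ddof=1)
    degenerate = sd == 0.0
    if degenerate:
        t = 0.0 if mean == 0.0 else float(np.sign(mean)) * DEGENERATE_T
    else:
        t = mean / (sd / np.sqrt(x.size))
    return (float(t), bool(degenerate)) if return_flag else float(t)


def pearson_r(x, y) -> float:
    """Product-moment correlation; errors on zero variance (undefined r)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length 1-D sequences of length >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.sqrt(xc @ xc)
    ny = np.sqrt(yc @ yc)
    if nx == 0.0 or ny == 0.0:
        raise ValueError("correlation undefined: an input has zero variance")
    r = float((xc @ yc) / (nx * ny))
    return float(np.clip(r, -1.0, 1.0))


def fisher_z(r):
    """Variance-stabilizing arctanh transform; |r| >= 1 is clamped with a
    warning rather than mapped to +-inf."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        warnings.warn("|r| >= 1 clamped to +-(1 - 1e-7) before Fisher Z",
                      stacklevel=2)
        r = np.clip(r, -(1 - 1e-7), 1 - 1e-7)
    z = np.arctanh(r)
    return float(z) if z.ndim == 0 else z


@dataclass
class PermutationResult:
    """Outcome of a seeded one-sided permutation test of a correlation."""

    observed_r: float
    permuted_p: float
    null_values: np.ndarray = field(repr=False)
    n_perm: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "observed_r": self.observed_r,
            "permuted_p": self.permuted_p,
            "n_perm": self.n_perm,
            "seed": self.seed,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)


def permutation_pvalue(scores, improvements, n_perm: int = 1000,
                       seed: int = 0) -> PermutationResult:
    """Correlate ``scores`` with ``improvements`` and validate by permutation.

    The null is built from ``n_perm`` independent uniform shuffles of the
    improvement scores. The p-value is one-sided (positive alternative:
    higher score predicts higher improvement) with the add-one rule
    p = (1 + #{null_r >= observed_r}) / (1 + n_perm), so p is never 0.
    """
    scores = np.asarray(scores, dtype=float)
    improvements = np.asarray(improvements, dtype=float)
    if scores.shape != improvements.shape or scores.size < 5:
        raise ValueError("need equal-length sequences of length >= 5")
    if np.ptp(improvements) == 0.0:
        raise ValueError("improvements are constant: correlation undefined "
                         "under permutation")
    observed = pearson_r(scores, improvements)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = pearson_r(scores, rng.permutation(improvements))
    p = (1.0 + np.count_nonzero(null >= observed)) / (1.0 + n_perm)
    return PermutationResult(observed_r=observed, permuted_p=float(p),
                             null_values=null, n_perm=n_perm, seed=seed)
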