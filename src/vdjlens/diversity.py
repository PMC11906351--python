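"""Repertoire-diversity statistics over fitted segment usage.

Shannon diversity and Jensen-Shannon divergence are computed in natural-log
units on the fitted V (or J) usage simplex; the 0.001 usage threshold is used
only for binary "selected segment" calls, and diversity comparisons are gated
on a minimum total lymphocyte fraction so that near-empty fits do not pass
as repertoires.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .vdj import VDJFit

SIMPLEX_TOL = 1e-8


class DiversityError(ValueError):
    pass


@dataclass
class SegmentUsageDistribution:
    """Probability distribution over V or J segment usage."""

    labels: list[str]
    probs: np.ndarray
    source: str = "V"   # "V" | "J"
    locus: str | None = None

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if len(self.labels) != len(self.probs):
            raise DiversityError("labels and probs must have equal length")
        if len(set(self.labels)) != len(self.labels):
            raise DiversityError("segment labels must be unique")
        if np.any(self.probs < -SIMPLEX_TOL) or abs(self.probs.sum() - 1.0) > SIMPLEX_TOL:
            raise DiversityError("usage vector is not a probability simplex")
        self.probs = np.clip(self.probs, 0.0, None)

    @classmethod
    def from_fit(cls, fit: VDJFit, source: str = "V") -> "SegmentUsageDistribution":
        usage = fit.v_usage if source == "V" else fit.j_usage
        return cls(labels=list(usage), probs=np.asarray(list(usage.values())),
                   source=source, locus=fit.locus)


def shannon_diversity(dist: SegmentUsageDistribution) -> float:
    """-sum p_i ln p_i in nats, with 0 ln 0 := 0."""
    p = dist.probs
    nz = p > 0
    return float(-np.sum(p[nz] * np.log(p[nz])))


def _kl(p: np.ndarray, m: np.ndarray) -> float:
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / m[nz])))


def jensen_shannon_divergence(P: SegmentUsageDistribution,
                              Q: SegmentUsageDistribution,
                              zero_fill: bool = True) -> float:
    """JSD(P||Q) = 1/2 D(P||M) + 1/2 D(Q||M), M = (P+Q)/2, natural log.

    Distributions over different label sets are aligned on the label union
    with zero fill unless ``zero_fill`` is disabled.
    """
    if P.labels == Q.labels:
        p, q = P.probs, Q.probs
    else:
        if not zero_fill:
            raise DiversityError("distributions have different label sets")
        labels = sorted(set(P.labels) | set(Q.labels))
        pd_ = dict(zip(P.labels, P.probs))
        qd_ = dict(zip(Q.labels, Q.probs))
        p = np.array([pd_.get(l, 0.0) for l in labels])
        q = np.array([qd_.get(l, 0.0) for l in labels])
    m = 0.5 * (p + q)
    return 0.5 * _kl(p, m) + 0.5 * _kl(q, m)


def selected_segments(dist: SegmentUsageDistribution, threshold: float = 0.001) -> set[str]:
    """Segments with fitted usage strictly above ``threshold``."""
    if threshold < 0:
        raise DiversityError("threshold must be non-negative")
    return {l for l, p in zip(dist.labels, dist.probs) if p > threshold}


def min_fraction_gate(fit: VDJFit, min_fraction: float = 0.05) -> bool:
    """True iff the fitted lymphocyte fraction strictly exceeds the gate."""
    return fit.fraction > min_fraction
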