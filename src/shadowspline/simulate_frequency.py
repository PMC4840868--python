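"""Frequency-based simulation of (n, s) shadow pairs.

A real sample's shadow pairs are summarized as a binned joint distribution:
read-count bins with probabilities p_j (unequal widths, so sparse high
counts do not produce near-empty bins) and, within each read bin, equal-
width shadow-count bins with probabilities q_kj.  Synthetic pairs are drawn
by a two-stage inverse-CDF scheme — one uniform picks the read bin and the
value within it, a second picks the shadow bin and value — which reproduces
the sample's joint (n, s) structure, including non-linear read-shadow
relationships that a calibration-style simulator cannot mimic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np

from .shadows import ShadowPairs

__all__ = [
    "FrequencyModel",
    "build_frequency_model",
    "sample_pairs",
    "expected_error_rate",
]

# width of the effectively-atomic shadow bin used when every shadow count
# in a read bin is identical (equal-width bins would otherwise degenerate)
_ATOM = 1e-9


@dataclass
class FrequencyModel:
    """Binned joint distribution of error-free read counts and shadow counts.

    ``read_edges``: M+1 strictly increasing edges; ``read_probs``: p_j.
    ``shadow_edges``: (M, L+1) per-read-bin equal-width edges;
    ``shadow_probs``: (M, L) conditional q_kj.  Bins are half-open
    [lo, hi) with the final bin closed.
    """

    read_edges: np.ndarray
    read_probs: np.ndarray
    shadow_edges: np.ndarray
    shadow_probs: np.ndarray

    def __post_init__(self) -> None:
        self.read_edges = np.asarray(self.read_edges, dtype=float)
        self.read_probs = np.asarray(self.read_probs, dtype=float)
        self.shadow_edges = np.atleast_2d(np.asarray(self.shadow_edges, dtype=float))
        self.shadow_probs = np.atleast_2d(np.asarray(self.shadow_probs, dtype=float))
        if np.any(np.diff(self.read_edges) <= 0):
            raise ValueError("read bin edges must be strictly increasing")
        if not np.isclose(self.read_probs.sum(), 1.0):
            raise ValueError("read-bin probabilities must sum to 1")
        for j, p in enumerate(self.read_probs):
            if p > 0:
                if np.any(np.diff(self.shadow_edges[j]) <= 0):
                    raise ValueError(f"shadow edges of read bin {j} not increasing")
                if not np.isclose(self.shadow_probs[j].sum(), 1.0):
                    raise ValueError(f"shadow probabilities of read bin {j} do not sum to 1")

    @property
    def n_read_bins(self) -> int:
        return self.read_probs.size

    @property
    def n_shadow_bins(self) -> int:
        return self.shadow_probs.shape[1]

    def analytic_expected_error_rate(self) -> float:
        """Cell-probability-weighted Sigma(s)/(Sigma(s)+Sigma(n)) in the
        infinite-sample limit: E[s]/(E[s]+E[n]) with cell-midpoint values."""
        read_mid = 0.5 * (self.read_edges[:-1] + self.read_edges[1:])
        mean_n = float(np.sum(self.read_probs * read_mid))
        shadow_mid = 0.5 * (self.shadow_edges[:, :-1] + self.shadow_edges[:, 1:])
        mean_s = float(np.sum(self.read_probs[:, None] * self.shadow_probs * shadow_mid))
        return mean_s / (mean_s + mean_n)

    def to_json(self, path: Union[str, Path]) -> None:
        payload = {
            "read_edges": self.read_edges.tolist(),
            "read_probs": self.read_probs.tolist(),
            "shadow_edges": self.shadow_edges.tolist(),
            "shadow_probs": self.shadow_probs.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "FrequencyModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            read_edges=np.array(payload["read_edges"]),
            read_probs=np.array(payload["read_probs"]),
            shadow_edges=np.array(payload["shadow_edges"]),
            shadow_probs=np.array(payload["shadow_probs"]),
        )


def _bin_index(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Half-open [lo, hi) binning with the final bin closed."""
    idx = np.searchsorted(edges, values, side="right") - 1
    idx[values == edges[-1]] = edges.size - 2
    return idx


def _resolve_read_edges(n: np.ndarray, spec: Union[str, np.ndarray]) -> np.ndarray:
    if isinstance(spec, str):
        if not spec.startswith("quantile:"):
            raise ValueError(f"unknown edge spec {spec!r}; use 'quantile:M' or an edge array")
        m_bins = int(spec.split(":", 1)[1])
        if m_bins < 1:
            raise ValueError("need at least one read bin")
        edges = np.unique(np.quantile(n, np.linspace(0, 1, m_bins + 1)))
        if edges.size < 2:  # all n identical
            edges = np.array([edges[0], edges[0] + _ATOM])
        edges[-1] += _ATOM  # keep the maximum inside the half-open scheme's last bin
        return edges
    edges = np.asarray(spec, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("read bin edges must be strictly increasing")
    if edges[0] > n.min() or edges[-1] < n.max():
        raise ValueError("read bin edges do not cover the observed count range")
    return edges


def build_frequency_model(
    pairs: ShadowPairs,
    read_edges: Union[str, np.ndarray] = "quantile:20",
    shadow_bins: int = 30,
) -> FrequencyModel:
    """Tabulate (n, s) pairs into the binned joint frequency model.

    ``read_edges`` is either an explicit strictly-increasing edge array or
    ``"quantile:M"`` for M bins at empirical quantiles of n (realizing the
    unequal widths that keep high-count bins populated).  Within each read
    bin, ``shadow_bins`` equal-width bins span that bin's shadow counts.
    Empty read bins get p_j = 0.
    """
    if shadow_bins < 1:
        raise ValueError("need at least one shadow bin per read bin")
    n, s = pairs.n, pairs.s
    edges = _resolve_read_edges(n, read_edges)
    m_bins = edges.size - 1
    idx = _bin_index(n, edges)
    counts = np.bincount(idx, minlength=m_bins).astype(float)
    read_probs = counts / counts.sum()

    shadow_edges = np.zeros((m_bins, shadow_bins + 1))
    shadow_probs = np.zeros((m_bins, shadow_bins))
    for j in range(m_bins):
        members = s[idx == j]
        if members.size == 0:
            shadow_edges[j] = np.arange(shadow_bins + 1, dtype=float)  # placeholder
            continue
        lo, hi = float(members.min()), float(members.max())
        if hi <= lo:
            hi = lo + _ATOM
        se = np.linspace(lo, hi, shadow_bins + 1)
        se[-1] += _ATOM
        k = _bin_index(members, se)
        q = np.bincount(k, minlength=shadow_bins).astype(float)
        shadow_edges[j] = se
        shadow_probs[j] = q / q.sum()
    return FrequencyModel(edges, read_probs, shadow_edges, shadow_probs)


def sample_pairs(
    model: FrequencyModel,
    n_pairs: int,
    rng=None,
    integer: bool = False,
) -> ShadowPairs:
    """Draw synthetic (n, s) pairs by the two-uniform inverse-CDF scheme.

    For each pair, U ~ uniform(0,1) picks the read bin j through the p_j
    CDF and n is uniform within that bin's edges; V ~ uniform(0,1) then
    picks the shadow bin k through the q_kj CDF and s is uniform within
    that bin.  ``integer=True`` rounds the draws to whole counts
    (shadow-regression inputs are counts; the fits are indifferent).
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if not np.any(model.read_probs > 0):
        raise ValueError("model has no populated read bin")
    rng = np.random.default_rng(rng)

    u = rng.uniform(size=n_pairs)
    read_cdf = np.cumsum(model.read_probs)
    j = np.searchsorted(read_cdf, u, side="right")
    j = np.minimum(j, model.n_read_bins - 1)
    n_lo = model.read_edges[j]
    n_hi = model.read_edges[j + 1]
    n_new = n_lo + rng.uniform(size=n_pairs) * (n_hi - n_lo)

    v = rng.uniform(size=n_pairs)
    shadow_cdf = np.cumsum(model.shadow_probs, axis=1)
    k = (shadow_cdf[j] <= v[:, None]).sum(axis=1)
    k = np.minimum(k, model.n_shadow_bins - 1)
    s_lo = model.shadow_edges[j, k]
    s_hi = model.shadow_edges[j, k + 1]
    s_new = s_lo + rng.uniform(size=n_pairs) * (s_hi - s_lo)

    if integer:
        n_new = np.maximum(np.rint(n_new), 1.0)
        s_new = np.maximum(np.rint(s_new), 0.0)
    return ShadowPairs(n=n_new, s=np.maximum(s_new, 0.0))


def expected_error_rate(pairs: ShadowPairs) -> float:
    """Expected per-read error rate Sigma(s) / (Sigma(s) + Sigma(n))."""
    total_s = float(pairs.s.sum())
    total_n = float(pairs.n.sum())
    if total_s + total_n <= 0:
        raise ValueError("pairs carry no counts")
    return total_s / (total_s + total_n)
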