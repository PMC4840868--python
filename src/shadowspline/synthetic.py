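"""Synthetic fixtures with machine-readable truth.

Generates sequencing samples that emulate the structure the estimators
face in practice — a skewed distinct-sequence abundance distribution,
fixed-length reads, per-position substitution errors — plus (n, s) pair
sets with controllable linear or non-linear shape.  Every fixture carries
its ground truth so tests validate against known values, never eyeballed
ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Union

import numpy as np

from .shadows import ShadowPairs
from .simulate_calibration import BaseErrorProfile

__all__ = [
    "FixtureSpec",
    "SampleTruth",
    "generate_sample",
    "generate_linear_pairs",
    "generate_nonlinear_pairs",
    "SHAPES",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class FixtureSpec:
    """Recipe for a synthetic sequencing sample.

    ``abundance`` is either a power-law exponent (source k gets weight
    (k+1)^-abundance, emulating the skewed distinct-sequence spectrum of
    transcriptome-style samples) or an explicit per-source count array.
    ``error_rate`` is a uniform per-base substitution probability or a
    per-position vector of length ``read_length``.
    """

    reference_length: int = 3000
    n_sources: int = 1200
    abundance: Union[float, np.ndarray] = 0.5
    read_length: int = 36
    error_rate: Union[float, np.ndarray] = 0.001
    total_reads: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reference_length < self.read_length:
            raise ValueError("reference shorter than read length")
        if self.n_sources < 1 or self.total_reads < 1 or self.read_length < 1:
            raise ValueError("sizes must be positive")
        if self.n_sources > self.reference_length - self.read_length + 1:
            raise ValueError("more sources than distinct reference positions")

    def profile(self) -> BaseErrorProfile:
        if np.isscalar(self.error_rate):
            return BaseErrorProfile.uniform(float(self.error_rate), self.read_length)
        return BaseErrorProfile(per_position_rate=np.asarray(self.error_rate))


@dataclass
class SampleTruth:
    """Ground truth for a generated sample, read by read."""

    reference: str
    source_sequences: list[str]
    source_counts: np.ndarray
    parent_index: np.ndarray  # per emitted read, index into source_sequences
    error_flags: np.ndarray   # per emitted read, True if >= 1 substitution

    @property
    def error_fraction(self) -> float:
        return float(self.error_flags.mean())

    def top_parent_indices(self, n_top: int) -> np.ndarray:
        """Indices of the ``n_top`` most abundant sources (count desc,
        sequence lexicographic tie-break, matching the ranking rule)."""
        order = sorted(
            range(len(self.source_sequences)),
            key=lambda i: (-int(self.source_counts[i]), self.source_sequences[i]),
        )
        return np.array(order[:n_top], dtype=np.int64)

    def error_fraction_among_top(self, n_top: int) -> float:
        """Fraction of error-bearing reads among reads parented by the
        top-``n_top`` sources — the truth the shadow pipeline's
        Sigma(s)/(Sigma(s)+Sigma(n)) estimates."""
        top = set(self.top_parent_indices(n_top).tolist())
        mask = np.isin(self.parent_index, list(top))
        if not mask.any():
            raise ValueError("no read parented by the top sources")
        return float(self.error_flags[mask].mean())

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "reference": self.reference,
                    "source_sequences": self.source_sequences,
                    "source_counts": self.source_counts.tolist(),
                    "parent_index": self.parent_index.tolist(),
                    "error_flags": self.error_flags.astype(int).tolist(),
                    "error_fraction": self.error_fraction,
                }
            )
        )


def _random_reference(rng, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def generate_sample(spec: FixtureSpec) -> tuple[str, SampleTruth]:
    """Generate a FASTQ sample (as text) plus its truth record.

    Source sequences are windows of a random reference; multiplicities
    follow the abundance law; each read copy independently receives
    substitution errors at the spec's per-position rates.  Deterministic
    for a given spec (single generator seeded from ``spec.seed``).
    """
    rng = np.random.default_rng(spec.seed)
    reference = _random_reference(rng, spec.reference_length)
    n_positions = spec.reference_length - spec.read_length + 1
    starts = rng.choice(n_positions, size=spec.n_sources, replace=False)
    sources = [reference[p : p + spec.read_length] for p in starts]
    # windows of a random reference collide with vanishing probability;
    # dedupe defensively so truth parentage stays unambiguous
    seen: set[str] = set()
    deduped = []
    for s in sources:
        if s not in seen:
            seen.add(s)
            deduped.append(s)
    sources = deduped

    if np.isscalar(spec.abundance):
        weights = (np.arange(len(sources)) + 1.0) ** (-float(spec.abundance))
        counts = rng.multinomial(spec.total_reads, weights / weights.sum())
    else:
        counts = np.asarray(spec.abundance, dtype=np.int64)
        if counts.size != len(sources):
            raise ValueError("explicit counts must match the number of sources")
    if counts.sum() == 0:
        raise ValueError("abundance law yielded zero reads")

    parent = np.repeat(np.arange(len(sources)), counts)
    mat = np.frombuffer("".join(sources).encode("ascii"), dtype=np.uint8).reshape(
        len(sources), spec.read_length
    )
    reads = mat[parent].copy()

    rates = spec.profile().per_position_rate
    flip = rng.random(reads.shape) < rates
    if flip.any():
        codes = np.searchsorted(_BASES, reads[flip])  # ACGT bytes are sorted
        shift = rng.integers(1, 4, size=codes.size)
        reads[flip] = _BASES[(codes + shift) % 4]
    error_flags = flip.any(axis=1)

    order = rng.permutation(reads.shape[0])
    reads = reads[order]
    parent = parent[order]
    error_flags = error_flags[order]

    qual = "I" * spec.read_length
    records = []
    for i in range(reads.shape[0]):
        seq = reads[i].tobytes().decode("ascii")
        records.append(f"@read{i}\n{seq}\n+\n{qual}\n")
    truth = SampleTruth(
        reference=reference,
        source_sequences=sources,
        source_counts=counts,
        parent_index=parent,
        error_flags=error_flags,
    )
    return "".join(records), truth


def generate_linear_pairs(
    slope: float,
    intercept: float = 0.0,
    noise: float = 0.0,
    m: int = 1000,
    n_range: tuple[int, int] = (100, 10000),
    seed=None,
) -> ShadowPairs:
    """Pairs with s = intercept + slope*n + Normal(0, noise), clamped at 0."""
    if slope < 0 or noise < 0:
        raise ValueError("slope and noise must be non-negative")
    if m < 4:
        raise ValueError("need m >= 4")
    rng = np.random.default_rng(seed)
    n = rng.integers(n_range[0], n_range[1] + 1, size=m).astype(float)
    s = intercept + slope * n
    if noise > 0:
        s = s + rng.normal(0.0, noise, size=m)
    return ShadowPairs(n=n, s=np.clip(s, 0.0, None))


def _shape_saturating(n: np.ndarray) -> np.ndarray:
    return 400.0 * n / (n + 300.0)


def _shape_linear(n: np.ndarray) -> np.ndarray:
    return 0.25 * n


def _shape_local_decrease(n: np.ndarray) -> np.ndarray:
    # high shadow counts at low n that fall before the linear trend takes
    # over — the pattern transcriptome samples show at small counts
    return 400.0 * np.exp(-n / 150.0) + 0.1 * n


SHAPES: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "linear": _shape_linear,
    "saturating": _shape_saturating,
    "local-decrease": _shape_local_decrease,
}


def generate_nonlinear_pairs(
    shape: str = "saturating",
    noise: float = 0.0,
    m: int = 500,
    n_range: tuple[int, int] = (1, 2000),
    seed=None,
) -> tuple[ShadowPairs, Callable[[np.ndarray], np.ndarray]]:
    """Pairs following a named read-shadow shape, plus the generating function.

    Shapes: ``linear``, ``saturating`` (monotone, flattening at high
    counts), ``local-decrease`` (shadows fall as counts rise at low n).
    """
    if shape not in SHAPES:
        raise ValueError(f"unknown shape {shape!r}; choose from {sorted(SHAPES)}")
    if m < 4:
        raise ValueError("need m >= 4")
    rng = np.random.default_rng(seed)
    fn = SHAPES[shape]
    n = np.sort(rng.integers(n_range[0], n_range[1] + 1, size=m)).astype(float)
    s = fn(n)
    if noise > 0:
        s = s + rng.normal(0.0, noise, size=m)
    return ShadowPairs(n=n, s=np.clip(s, 0.0, None)), fn
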