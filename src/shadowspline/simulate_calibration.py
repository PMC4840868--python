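"""Calibration-style simulation: per-position substitution errors.

The alternative to the frequency-based simulator: take reads presumed error
free, inject substitution errors position by position at a base-specific
error profile, and re-tally.  The profile itself can be estimated from
reads anchored exactly (or near exactly) on a small reference such as the
5.4 kb PhiX genome.  Polymorphism and tandem-duplication perturbations of
the "error-free" truth let the robustness of downstream estimates to
reference-sample divergence be probed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .readcounts import ReadCountTable

__all__ = [
    "BaseErrorProfile",
    "estimate_base_profile",
    "inject_errors",
    "apply_polymorphisms",
    "apply_duplications",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = {65: 0, 67: 1, 71: 2, 84: 3}  # A C G T


def _encode_strings(seqs: Sequence[str], length: int) -> np.ndarray:
    flat = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    return flat.reshape(len(seqs), length)


@dataclass
class BaseErrorProfile:
    """Per-position substitution probabilities along the read.

    A flipped base is replaced uniformly by one of the 3 alternatives.
    ``n_anchored`` / ``n_skipped`` record provenance when the profile was
    estimated from reference-anchored reads.
    """

    per_position_rate: np.ndarray
    n_anchored: int = 0
    n_skipped: int = 0

    def __post_init__(self) -> None:
        self.per_position_rate = np.asarray(self.per_position_rate, dtype=float)
        if self.per_position_rate.ndim != 1 or self.per_position_rate.size == 0:
            raise ValueError("profile must be a non-empty 1-D rate vector")
        if np.any((self.per_position_rate < 0) | (self.per_position_rate > 1)):
            raise ValueError("rates must lie in [0, 1]")

    @property
    def read_length(self) -> int:
        return self.per_position_rate.size

    def to_tsv(self, path: Union[str, Path]) -> None:
        pd.DataFrame(
            {"position": np.arange(self.read_length), "rate": self.per_position_rate}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "BaseErrorProfile":
        df = pd.read_csv(path, sep="\t")
        df = df.sort_values("position")
        return cls(per_position_rate=df["rate"].to_numpy())

    @classmethod
    def uniform(cls, rate: float, read_length: int) -> "BaseErrorProfile":
        return cls(per_position_rate=np.full(read_length, rate))


def _as_seq_count_list(reads) -> list[tuple[str, int]]:
    if isinstance(reads, ReadCountTable):
        return list(reads.entries.items())
    out = []
    for item in reads:
        if isinstance(item, str):
            out.append((item, 1))
        else:
            seq, cnt = item
            out.append((seq, int(cnt)))
    return out


def estimate_base_profile(reads, reference: str) -> BaseErrorProfile:
    """Estimate per-position substitution rates against a small reference.

    Each distinct read is placed at every reference offset (forward strand,
    linear scan — suitable for references up to ~1e6 bases); the placement
    minimizing mismatches is its anchor.  Reads whose minimal placement is
    not unique are skipped and counted.  ``rate[p]`` is the multiplicity-
    weighted fraction of anchored reads mismatching the reference at read
    position p.
    """
    items = _as_seq_count_list(reads)
    if not items:
        raise ValueError("no reads supplied")
    length = len(items[0][0])
    reference = reference.upper()
    if len(reference) < length:
        raise ValueError("reference shorter than the read length")
    ref = np.frombuffer(reference.encode("ascii"), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(ref, length)  # (W, L)

    # exact-match fast path: unique window substrings anchor at distance 0
    window_pos: dict[str, int] = {}
    ambiguous: set[str] = set()
    for pos in range(len(reference) - length + 1):
        sub = reference[pos : pos + length]
        if sub in window_pos:
            ambiguous.add(sub)
        window_pos[sub] = pos

    mism_counts = np.zeros(length, dtype=float)
    n_anchored = 0
    n_skipped = 0
    anchored_weight = 0.0
    scan_items = []
    for seq, cnt in items:
        if len(seq) != length:
            raise ValueError("reads must have equal length")
        if seq in window_pos:
            if seq in ambiguous:
                n_skipped += 1
            else:
                n_anchored += 1
                anchored_weight += cnt
            continue
        scan_items.append((seq, cnt))

    # blocked all-offsets scan for the reads without an exact placement
    block = 64
    for start in range(0, len(scan_items), block):
        chunk = scan_items[start : start + block]
        reads_mat = _encode_strings([s for s, _ in chunk], length)
        mism = windows[None, :, :] != reads_mat[:, None, :]  # (B, W, L)
        dist = mism.sum(axis=2)
        best = dist.min(axis=1)
        for b, (_, cnt) in enumerate(chunk):
            where = np.flatnonzero(dist[b] == best[b])
            if where.size != 1:
                n_skipped += 1
                continue
            n_anchored += 1
            anchored_weight += cnt
            mism_counts += cnt * mism[b, where[0]]
    if n_anchored == 0:
        raise ValueError("no read could be uniquely anchored on the reference")
    return BaseErrorProfile(
        per_position_rate=mism_counts / anchored_weight,
        n_anchored=n_anchored,
        n_skipped=n_skipped,
    )


def inject_errors(reads_with_counts, profile: BaseErrorProfile, rng=None) -> ReadCountTable:
    """Inject substitution errors into every read copy independently.

    Each base of each copy flips with its positional probability to one of
    the 3 alternative bases, chosen uniformly.  ``N`` bases are left
    untouched.  The total read count is conserved.
    """
    rng = np.random.default_rng(rng)
    items = _as_seq_count_list(reads_with_counts)
    if not items:
        raise ValueError("no reads supplied")
    length = len(items[0][0])
    if profile.read_length != length:
        raise ValueError(
            f"profile length {profile.read_length} != read length {length}"
        )
    seqs = [s for s, _ in items]
    counts = np.array([c for _, c in items], dtype=np.int64)
    mat = _encode_strings(seqs, length)
    expanded = np.repeat(mat, counts, axis=0)  # one row per read copy

    rates = profile.per_position_rate
    flip = rng.random(expanded.shape) < rates
    is_acgt = (
        (expanded == 65) | (expanded == 67) | (expanded == 71) | (expanded == 84)
    )
    flip &= is_acgt
    if flip.any():
        codes = np.zeros_like(expanded)
        for byte, code in _CODE.items():
            codes[expanded == byte] = code
        shift = rng.integers(1, 4, size=int(flip.sum()))
        codes[flip] = (codes[flip] + shift) % 4
        expanded = np.where(is_acgt, _BASES[codes], expanded)

    entries: dict[str, int] = {}
    for row in expanded:
        seq = row.tobytes().decode("ascii")
        entries[seq] = entries.get(seq, 0) + 1
    return ReadCountTable(entries=entries, read_length=length)


def _perturb_sites(seqs: list[str], rate: float, rng) -> list[tuple[int, int]]:
    """Draw round(total_bases * rate) distinct (sequence, position) sites."""
    lengths = np.array([len(s) for s in seqs], dtype=np.int64)
    total = int(lengths.sum())
    k = int(round(total * rate))
    if k == 0:
        return []
    flat = rng.choice(total, size=k, replace=False)
    bounds = np.cumsum(lengths)
    out = []
    for pos in np.sort(flat):
        i = int(np.searchsorted(bounds, pos, side="right"))
        offset = int(pos - (bounds[i - 1] if i > 0 else 0))
        out.append((i, offset))
    return out


def apply_polymorphisms(sequences, rate: float = 0.001, rng=None):
    """Substitute bases at the stated density (default 1 per 1000 bp).

    ``round(total_bases * rate)`` positions are drawn without replacement
    over the pooled bases of the input; each receives a random alternative
    base.  A single string input returns a string; the perturbed sequences
    are the new "error-free" truth for downstream simulation.
    """
    single = isinstance(sequences, str)
    seqs = [sequences] if single else list(sequences)
    if rate < 0:
        raise ValueError("rate must be >= 0")
    rng = np.random.default_rng(rng)
    out = [bytearray(s.encode("ascii")) for s in seqs]
    for i, pos in _perturb_sites(seqs, rate, rng):
        old = chr(out[i][pos])
        alternatives = [b for b in "ACGT" if b != old]
        out[i][pos] = ord(alternatives[int(rng.integers(0, len(alternatives)))])
    result = [b.decode("ascii") for b in out]
    return result[0] if single else result


def apply_duplications(sequences, rate: float = 0.002, rng=None):
    """Tandem-duplicate bases at the stated density (default 2 per 1000 bp).

    ``round(total_bases * rate)`` positions are drawn without replacement;
    each chosen base is duplicated in place and the sequence is truncated
    back to its original length, preserving fixed read lengths.
    """
    single = isinstance(sequences, str)
    seqs = [sequences] if single else list(sequences)
    if rate < 0:
        raise ValueError("rate must be >= 0")
    rng = np.random.default_rng(rng)
    sites: dict[int, list[int]] = {}
    for i, pos in _perturb_sites(seqs, rate, rng):
        sites.setdefault(i, []).append(pos)
    out = []
    for i, s in enumerate(seqs):
        if i in sites:
            original_len = len(s)
            # apply right-to-left so earlier positions stay valid
            for pos in sorted(sites[i], reverse=True):
                s = s[: pos + 1] + s[pos] + s[pos + 1 :]
            s = s[:original_len]
        out.append(s)
    return out[0] if single else out
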