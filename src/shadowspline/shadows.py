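"""Error-free read selection and shadow counting.

The most abundant sequences in a sample are presumed error free; a *shadow*
is any other read within two substitutions of one of them.  The count of
shadows attached to each error-free sequence, paired with that sequence's
own count, is the raw observation the error-rate models consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .readcounts import ReadCountTable, rank_sequences

__all__ = ["ErrorFreeSet", "ShadowPairs", "select_error_free", "hamming", "assign_shadows"]

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_N_CODE = 4


@dataclass
class ErrorFreeSet:
    """Top-ranked, N-free sequences of a sample with their counts.

    ``members`` is ordered by descending count (lexicographic tie-break),
    i.e. by the rank order of the source table.
    """

    members: list[tuple[str, int]]
    capacity: int = 1000

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("error-free set is empty")
        if len(self.members) > self.capacity:
            raise ValueError("more members than capacity")
        counts = [c for _, c in self.members]
        if any(c2 > c1 for c1, c2 in zip(counts, counts[1:])):
            raise ValueError("members must be ordered by non-increasing count")
        lengths = {len(s) for s, _ in self.members}
        if len(lengths) != 1:
            raise ValueError("member sequences must have equal length")
        if any("N" in s for s, _ in self.members):
            raise ValueError("error-free sequences must be N-free")

    def __len__(self) -> int:
        return len(self.members)

    @property
    def sequences(self) -> list[str]:
        return [s for s, _ in self.members]

    @property
    def counts(self) -> np.ndarray:
        return np.array([c for _, c in self.members], dtype=np.int64)


@dataclass
class ShadowPairs:
    """Ordered (error-free count n_i, shadow count s_i) observations.

    Sorted by n ascending; ties in n are kept as separate observations in
    stable order.  Values may be non-integer when produced by the
    frequency-based simulator.
    """

    n: np.ndarray
    s: np.ndarray

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        if self.n.ndim != 1 or self.n.shape != self.s.shape:
            raise ValueError("n and s must be 1-D arrays of equal length")
        if self.n.size == 0:
            raise ValueError("empty pairs")
        if np.any(self.n < 1):
            raise ValueError("all error-free counts n must be >= 1")
        if np.any(self.s < 0):
            raise ValueError("shadow counts s must be >= 0")
        if np.any(np.diff(self.n) < 0):
            order = np.argsort(self.n, kind="stable")
            self.n = self.n[order]
            self.s = self.s[order]

    def __len__(self) -> int:
        return self.n.size

    @property
    def m(self) -> int:
        return self.n.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"n": self.n, "s": self.s})

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "ShadowPairs":
        df = pd.read_csv(path, sep="\t")
        if not {"n", "s"}.issubset(df.columns):
            raise ValueError(f"{path}: expected columns 'n' and 's'")
        return cls(n=df["n"].to_numpy(), s=df["s"].to_numpy())


def select_error_free(table: ReadCountTable, n_top: int = 1000) -> ErrorFreeSet:
    """Select the top ``n_top`` most frequent N-free sequences as error free.

    Sequences containing N are never eligible: an uncalled base cannot
    anchor mismatch counting.  Returns fewer than ``n_top`` members when the
    sample has fewer eligible distinct sequences.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    members = [(seq, cnt) for seq, cnt in rank_sequences(table) if "N" not in seq]
    if not members:
        raise ValueError("no N-free sequence available for the error-free set")
    return ErrorFreeSet(members=members[:n_top], capacity=n_top)


def hamming(a: str, b: str) -> int:
    """Substitution distance between equal-length sequences.

    Any position where either symbol is ``N`` counts as a mismatch (an
    uncalled base cannot be confirmed to agree).
    """
    if len(a) != len(b):
        raise ValueError(f"sequences have unequal lengths {len(a)} and {len(b)}")
    return sum(x != y or x == "N" or y == "N" for x, y in zip(a, b))


def _encode(seqs: Sequence[str], length: int) -> np.ndarray:
    flat = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    mat = flat.reshape(len(seqs), length)
    out = np.empty_like(mat)
    for base, code in _BASE_CODE.items():
        out[mat == ord(base)] = code
    return out


def assign_shadows(
    table: ReadCountTable,
    efset: ErrorFreeSet,
    max_mismatch: int = 2,
    unique_assignment: bool = True,
) -> ShadowPairs:
    """Count, for each error-free sequence, the reads within ``max_mismatch``.

    Every distinct non-error-free sequence within distance ``max_mismatch``
    of at least one error-free sequence contributes its full multiplicity.
    Under ``unique_assignment`` (default) it is attributed to exactly one
    error-free sequence — nearest; ties to the higher-count one; remaining
    ties lexicographic — so no read is double counted.  With
    ``unique_assignment=False`` it is counted toward every error-free
    sequence within range.  Error-free members themselves are never shadows.

    The result is sorted by n ascending and is invariant to the record
    order of the input sample.
    """
    if max_mismatch < 1:
        raise ValueError("max_mismatch must be >= 1")
    length = table.read_length
    ef_seqs = efset.sequences
    ef_counts = efset.counts
    ef_index = {s: i for i, s in enumerate(ef_seqs)}

    others = [(seq, cnt) for seq, cnt in table.entries.items() if seq not in ef_index]
    shadow_totals = np.zeros(len(ef_seqs), dtype=np.int64)

    if others:
        other_seqs = [s for s, _ in others]
        other_counts = np.array([c for _, c in others], dtype=np.int64)
        reads = _encode(other_seqs, length)          # (D, L)
        reads_is_n = reads == _N_CODE
        ef_mat = _encode(ef_seqs, length)            # (E, L)

        n_reads = reads.shape[0]
        best_dist = np.full(n_reads, max_mismatch + 1, dtype=np.int32)
        best_ef = np.full(n_reads, -1, dtype=np.int64)
        # efset members are in rank order (count desc, lex asc), so the first
        # member reaching the minimal distance realizes the documented
        # tie-break; strict "<" updates keep it.
        for j in range(ef_mat.shape[0]):
            mism = (reads != ef_mat[j]) | reads_is_n
            dist = mism.sum(axis=1, dtype=np.int32)
            if unique_assignment:
                better = dist < best_dist
                best_dist[better] = dist[better]
                best_ef[better] = j
            else:
                within = dist <= max_mismatch
                shadow_totals[j] += int(other_counts[within].sum())
        if unique_assignment:
            assigned = best_ef >= 0
            np.add.at(shadow_totals, best_ef[assigned], other_counts[assigned])

    return ShadowPairs(n=ef_counts.astype(float), s=shadow_totals.astype(float))
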