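"""Replicate driver: simulation studies and single-sample pipelines.

The simulation protocol mirrors the evaluation design: from a frequency
model of a sample's shadow pairs, draw many replicates of 1000 pairs each,
estimate SRER / EER_CS / EER_RS on every replicate, and report the medians
together with the median expected error rate and the absolute biases.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np

from .model import ShadowErrorModel, ShadowErrorResults
from .readcounts import ReadCountTable, count_reads, read_counts
from .shadows import ShadowPairs
from .simulate_frequency import FrequencyModel, expected_error_rate, sample_pairs

__all__ = ["StudySummary", "run_simulation_study", "run_real_sample"]

_METHODS = ("srer", "eer_cs", "eer_rs")


@dataclass
class StudySummary:
    """Medians over replicates, absolute biases, and bookkeeping."""

    medians: dict
    biases: dict
    iqr: dict
    n_replicates: int
    n_failed: int
    seed: int

    def __post_init__(self) -> None:
        for k, v in self.biases.items():
            if v < 0:
                raise ValueError(f"bias {k} negative")

    def to_dict(self) -> dict:
        return {
            "expected_er": self.medians["expected_er"],
            "srer": self.medians["srer"],
            "srer_bias": self.biases["srer"],
            "eer_cs": self.medians["eer_cs"],
            "eer_cs_bias": self.biases["eer_cs"],
            "eer_rs": self.medians["eer_rs"],
            "eer_rs_bias": self.biases["eer_rs"],
            "iqr": self.iqr,
            "replicates": self.n_replicates,
            "failed_replicates": self.n_failed,
            "seed": self.seed,
        }

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def run_simulation_study(
    model: FrequencyModel,
    replicates: int = 1000,
    pairs_per_rep: int = 1000,
    seed: int = 0,
    lam: Union[float, str] = "auto",
    eer_draws: int = 1000,
    integer_pairs: bool = False,
) -> StudySummary:
    """Monte-Carlo evaluation of the estimators against a frequency model.

    Per replicate: draw ``pairs_per_rep`` pairs, compute the expected error
    rate of the draw and the three estimates.  Replicate seeds are spawned
    from the master seed, so each replicate is independent and re-runnable.
    A replicate whose estimator fails (e.g. spline degeneracy) is skipped
    and counted.  Biases are |median estimate - median expected ER|.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    children = np.random.SeedSequence(seed).spawn(replicates)
    values: dict[str, list[float]] = {k: [] for k in ("expected_er",) + _METHODS}
    n_failed = 0
    for child in children:
        rng = np.random.default_rng(child)
        try:
            pairs = sample_pairs(model, pairs_per_rep, rng=rng, integer=integer_pairs)
            results = ShadowErrorModel(pairs).fit(lam=lam, eer_draws=eer_draws, seed=rng)
        except (ValueError, np.linalg.LinAlgError):
            n_failed += 1
            continue
        values["expected_er"].append(expected_error_rate(pairs))
        values["srer"].append(results.srer)
        values["eer_cs"].append(results.eer_cs)
        values["eer_rs"].append(results.eer_rs)
    if not values["expected_er"]:
        raise RuntimeError("every replicate failed")
    medians = {k: float(np.median(v)) for k, v in values.items()}
    iqr = {
        k: [float(np.percentile(v, 25)), float(np.percentile(v, 75))]
        for k, v in values.items()
    }
    biases = {k: abs(medians[k] - medians["expected_er"]) for k in _METHODS}
    return StudySummary(
        medians=medians,
        biases=biases,
        iqr=iqr,
        n_replicates=replicates - n_failed,
        n_failed=n_failed,
        seed=seed,
    )


def run_real_sample(
    source,
    top_n: int = 1000,
    max_mismatch: int = 2,
    lam: Union[float, str] = "auto",
    eer_draws: int = 1000,
    seed: int = 0,
) -> tuple[ShadowErrorResults, ShadowPairs]:
    """Full pipeline on one sample: counts -> shadows -> estimates.

    ``source`` may be a ``ReadCountTable``, a path to a count TSV, or a
    path to a FASTQ file (detected by suffix).  Returns the fitted results
    and the derived shadow pairs.
    """
    if isinstance(source, ReadCountTable):
        table = source
    else:
        path = Path(source)
        if path.suffix in (".tsv", ".txt", ".counts"):
            table = read_counts(path)
        else:
            table = count_reads(path)
    model = ShadowErrorModel.from_counts(table, top_n=top_n, max_mismatch=max_mismatch)
    results = model.fit(lam=lam, eer_draws=eer_draws, seed=seed)
    return results, model.pairs
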