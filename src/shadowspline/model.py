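"""Model/Results front end for shadow-based error-rate estimation.

``ShadowErrorModel`` holds the (n, s) observations — built directly, from a
DataFrame, from a read-count table, or from a FASTQ file — and ``fit()``
runs the three estimators (robust linear SRER, cubic-spline EER, robust-
spline EER), returning a ``ShadowErrorResults`` with the estimates,
convergence diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import error_models as em
from .readcounts import ReadCountTable, count_reads
from .shadows import ShadowPairs, assign_shadows, select_error_free
from .simulate_frequency import expected_error_rate

__all__ = ["ShadowErrorModel", "ShadowErrorResults"]


class ShadowErrorModel:
    """Error-rate model for one sample's shadow pairs.

    Parameters
    ----------
    pairs : ShadowPairs
        Observations (error-free count n_i, shadow count s_i).
    """

    def __init__(self, pairs: ShadowPairs):
        self.pairs = pairs

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, n_col: str = "n", s_col: str = "s"):
        return cls(ShadowPairs(n=df[n_col].to_numpy(), s=df[s_col].to_numpy()))

    @classmethod
    def from_counts(
        cls,
        table: ReadCountTable,
        top_n: int = 1000,
        max_mismatch: int = 2,
        unique_assignment: bool = True,
    ):
        """Build pairs from a read-count table: top-``top_n`` sequences are
        the error-free set, shadows are reads within ``max_mismatch``."""
        efset = select_error_free(table, top_n)
        pairs = assign_shadows(table, efset, max_mismatch, unique_assignment)
        return cls(pairs)

    @classmethod
    def from_fastq(cls, path, top_n: int = 1000, max_mismatch: int = 2):
        return cls.from_counts(count_reads(path), top_n=top_n, max_mismatch=max_mismatch)

    def fit(
        self,
        lam: Union[float, str] = "auto",
        eer_draws: int = 1000,
        seed=None,
        max_iter: int = 50,
        tol: float = 1e-6,
        eer_scheme: str = "integer-range",
    ) -> "ShadowErrorResults":
        """Fit all three estimators and assemble the error-rate estimates.

        ``seed`` drives the EER count sampling (an int, a Generator, or
        None).  Both EER variants reuse the same draws so that the cubic
        vs robust comparison is paired.
        """
        pairs = self.pairs
        linear = em.fit_shadow_linear(pairs)
        srer_rate = em.srer(linear)

        cubic = em.fit_cubic_spline(pairs, em.SplineConfig(method="cubic", lam=lam))
        robust = em.fit_robust_spline(
            pairs, em.SplineConfig(method="robust", lam=lam, max_iter=max_iter, tol=tol)
        )
        rng = np.random.default_rng(seed)
        eer_seed = rng.integers(0, 2**31)
        eer_cs, samples_cs = em.sample_eer(
            cubic, pairs, draws=eer_draws, rng=np.random.default_rng(eer_seed), scheme=eer_scheme
        )
        eer_rs, samples_rs = em.sample_eer(
            robust, pairs, draws=eer_draws, rng=np.random.default_rng(eer_seed), scheme=eer_scheme
        )
        estimate = em.ErrorRateEstimate(
            srer=srer_rate,
            eer_cs=eer_cs,
            eer_rs=eer_rs,
            expected_er=expected_error_rate(pairs),
            per_count_samples={"cubic": samples_cs, "robust": samples_rs},
        )
        estimate.compute_biases()
        return ShadowErrorResults(self, estimate, linear, cubic, robust)


class ShadowErrorResults:
    """Fitted estimates, diagnostics and reporting for one sample."""

    def __init__(
        self,
        model: ShadowErrorModel,
        estimate: em.ErrorRateEstimate,
        linear_fit: em.LinearFit,
        cubic_curve: em.FittedCurve,
        robust_curve: em.FittedCurve,
    ):
        self.model = model
        self.estimate = estimate
        self.linear_fit = linear_fit
        self.cubic_curve = cubic_curve
        self.robust_curve = robust_curve

    # -- scalar accessors ---------------------------------------------------
    @property
    def srer(self) -> float:
        return self.estimate.srer

    @property
    def eer_cs(self) -> float:
        return self.estimate.eer_cs

    @property
    def eer_rs(self) -> float:
        return self.estimate.eer_rs

    @property
    def expected_er(self) -> Optional[float]:
        return self.estimate.expected_er

    @property
    def biases(self) -> dict:
        return self.estimate.biases

    # -- reporting ----------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "srer": self.srer,
            "eer_cs": self.eer_cs,
            "eer_rs": self.eer_rs,
            "expected_er": self.expected_er,
            "biases": self.biases,
            "linear": {
                "intercept": self.linear_fit.intercept,
                "slope": self.linear_fit.slope,
                "converged": self.linear_fit.converged,
                "iterations": self.linear_fit.iterations,
            },
            "cubic_spline": {
                "lambda": self.cubic_curve.lam_value,
                "auto": self.cubic_curve.lam == "auto",
            },
            "robust_spline": {
                "lambda": self.robust_curve.lam_value,
                "auto": self.robust_curve.lam == "auto",
                "converged": self.robust_curve.converged,
                "iterations": self.robust_curve.iterations,
            },
            "m": self.model.pairs.m,
        }

    def to_json(self, path, include_samples: bool = True) -> None:
        payload = self.to_dict()
        if include_samples:
            payload["per_count_samples"] = self.estimate.per_count_samples
        Path(path).write_text(json.dumps(payload, indent=2))

    def summary(self) -> str:
        d = self.to_dict()
        lines = [
            "Shadow error-rate estimates",
            "===========================",
            f"observations (m):           {d['m']}",
            f"count range [n_1, n_m]:     [{self.model.pairs.n[0]:g}, {self.model.pairs.n[-1]:g}]",
            "",
            f"SRER   (robust linear):     {self.srer:.4f}",
            f"EER_CS (cubic spline):      {self.eer_cs:.4f}",
            f"EER_RS (robust spline):     {self.eer_rs:.4f}",
            f"expected ER (sum s/(s+n)):  {self.expected_er:.4f}",
            "",
            f"linear fit: intercept={self.linear_fit.intercept:.4g} "
            f"slope={self.linear_fit.slope:.4g} "
            f"converged={self.linear_fit.converged}",
            f"cubic spline:  lambda={self.cubic_curve.lam_value:.4g}"
            + (" (GCV)" if self.cubic_curve.lam == "auto" else ""),
            f"robust spline: lambda={self.robust_curve.lam_value:.4g}"
            + (" (GCV)" if self.robust_curve.lam == "auto" else "")
            + f", {self.robust_curve.iterations} reweighting iterations, "
            f"converged={self.robust_curve.converged}",
        ]
        if self.biases:
            lines.append("")
            lines.append(
                "absolute biases vs expected ER: "
                + ", ".join(f"{k}={v:.4f}" for k, v in self.biases.items())
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Scatter of (n, s) with both fitted spline curves and the robust line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        pairs = self.model.pairs
        ax.scatter(pairs.n, pairs.s, s=8, alpha=0.4, label="observed")
        grid = np.linspace(pairs.n[0], pairs.n[-1], 400)
        ax.plot(grid, self.cubic_curve(grid), label="cubic spline")
        ax.plot(grid, self.robust_curve(grid), label="robust spline", ls="--")
        ax.plot(
            grid,
            self.linear_fit.intercept + self.linear_fit.slope * grid,
            label="robust linear",
            ls=":",
        )
        ax.set_xlabel("error-free read count n")
        ax.set_ylabel("shadow count s")
        ax.legend()
        return ax
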