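"""Sloan neutral community model on occupancy-abundance clouds.

Under neutral assembly, the local relative abundance of a taxon whose mean
relative abundance in the source community is *p* follows a beta
distribution Beta(N·m·p, N·m·(1−p)), where N is the sampling depth in reads
and m the migration (dispersal) parameter.  The probability of detecting
the taxon — i.e. its expected occupancy — is the probability that this
local abundance exceeds the detection limit d/N:

    occupancy(p) = 1 − F_Beta(d/N; N·m·p, N·m·(1−p))

The single free parameter m is fitted by least squares on the occupancy
scale, and a 95% envelope around the fitted curve (Wilson score bounds at
the observed number of samples) classifies each taxon as above, within or
below the neutral expectation.  Taxa above the envelope are more prevalent
than their abundance explains (deterministic selection or active dispersal,
e.g. by arthropods moving through a greenhouse); taxa below are dispersal
limited.

The model is exposed statsmodels-style: build a
:class:`NeutralCommunityModel` from occupancy-abundance records (or a
count table), call :meth:`~NeutralCommunityModel.fit`, and read the
estimates off the returned :class:`NeutralFitResults`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core_taxa import OccupancyAbundanceRecord, occupancy_abundance
from .datamodel import AsvTable

__all__ = [
    "NeutralCommunityModel",
    "NeutralFitResults",
    "predict_occupancy",
    "fit_neutral",
]

_LOG_M_BOUNDS = (np.log10(1e-4), np.log10(1e2))


def predict_occupancy(
    p: float | np.ndarray, m: float, N: float, d: float = 1.0
) -> float | np.ndarray:
    """Expected occupancy of a taxon with source mean relative abundance ``p``.

    Parameters
    ----------
    p : mean relative abundance, in (0, 1)
    m : migration parameter, > 0
    N : sampling depth in reads, >= 1
    d : detection limit in reads (a taxon is detected at >= d reads), in [1, N)
    """
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr <= 0) | (p_arr >= 1)):
        raise ValueError("mean relative abundance must lie strictly in (0, 1)")
    if m <= 0:
        raise ValueError("migration parameter m must be positive")
    if N < 1:
        raise ValueError("depth N must be >= 1")
    if not 1 <= d < N:
        raise ValueError("detection limit d must satisfy 1 <= d < N")
    out = stats.beta.sf(d / N, N * m * p_arr, N * m * (1.0 - p_arr))
    return float(out) if np.isscalar(p) else out


class NeutralCommunityModel:
    """Sloan neutral model for an occupancy-abundance cloud.

    Parameters
    ----------
    records
        Occupancy-abundance records (one per taxon).  Taxa with zero
        occupancy or with mean abundance outside (0, 1) are excluded from
        the fit but kept in the results table.
    N
        Effective sampling depth in reads; in the standard pipeline this is
        the rarefaction depth (every sample then has exactly N reads).
    d
        Detection limit in reads (default 1: detected at a single read).
    n_samples
        Number of samples behind the occupancy estimates; sets the width of
        the 95% envelope.  Defaults to the smallest integer consistent with
        the occupancy resolution, but passing it explicitly is preferred.
    """

    def __init__(
        self,
        records: Sequence[OccupancyAbundanceRecord],
        N: float,
        d: float = 1.0,
        n_samples: int | None = None,
    ) -> None:
        if not records:
            raise ValueError("no occupancy-abundance records supplied")
        self.records = list(records)
        self.N = float(N)
        self.d = float(d)
        if n_samples is None:
            occs = [r.occupancy for r in self.records if 0 < r.occupancy < 1]
            n_samples = (
                int(round(1 / min(min(occs), 1 - max(occs)))) if occs else 1
            )
        self.n_samples = int(n_samples)
        self._p = np.array([r.mean_relative_abundance for r in self.records])
        self._occ = np.array([r.occupancy for r in self.records])
        self._fit_mask = (self._p > 0) & (self._p < 1) & (self._occ > 0)

    @classmethod
    def from_table(
        cls, table: AsvTable, N: float | None = None, d: float = 1.0
    ) -> "NeutralCommunityModel":
        """Build the model from a (rarefied) count table.

        With uniform library sizes (post-rarefaction) the depth N defaults
        to that common total.
        """
        totals = table.sample_totals()
        if N is None:
            if totals.nunique() != 1:
                raise ValueError(
                    "library sizes are unequal; pass the effective depth N explicitly"
                )
            N = float(totals.iloc[0])
        records = occupancy_abundance(table)
        return cls(records, N=N, d=d, n_samples=table.n_samples)

    def sse(self, m: float) -> float:
        """Sum of squared occupancy residuals at migration parameter ``m``."""
        pred = predict_occupancy(self._p[self._fit_mask], m, self.N, self.d)
        return float(np.sum((self._occ[self._fit_mask] - pred) ** 2))

    def fit(self) -> "NeutralFitResults":
        """Least-squares fit of m by bounded search on log10 m."""
        if self._fit_mask.sum() < 10:
            raise ValueError(
                f"need >= 10 fittable taxa (0 < occupancy, 0 < abundance < 1); "
                f"have {int(self._fit_mask.sum())}"
            )
        occ_fit = self._occ[self._fit_mask]
        if np.all(occ_fit == occ_fit[0]):
            raise ValueError("degenerate occupancy cloud; neutral fit undefined")
        res = optimize.minimize_scalar(
            lambda log_m: self.sse(10.0 ** log_m),
            bounds=_LOG_M_BOUNDS,
            method="bounded",
            options={"xatol": 1e-8},
        )
        m_hat = float(10.0 ** res.x)
        sse = self.sse(m_hat)
        ss_tot = float(np.sum((occ_fit - occ_fit.mean()) ** 2))
        r_squared = 1.0 - sse / ss_tot
        return NeutralFitResults(model=self, m=m_hat, r_squared=r_squared)


@dataclass
class NeutralFitResults:
    """Fitted neutral model: point estimate, goodness of fit and the
    per-taxon classification against the 95% envelope."""

    model: NeutralCommunityModel
    m: float
    r_squared: float

    @property
    def N(self) -> float:
        return self.model.N

    @property
    def d(self) -> float:
        return self.model.d

    def predict(self, p: float | np.ndarray) -> float | np.ndarray:
        """Predicted occupancy at mean relative abundance ``p``."""
        return predict_occupancy(p, self.m, self.N, self.d)

    def envelope(self, p: float | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """95% Wilson score bounds on the predicted occupancy, at the
        number of samples behind the observed occupancies."""
        pred = np.atleast_1d(np.asarray(self.predict(p), dtype=float))
        n = max(self.model.n_samples, 1)
        z = stats.norm.ppf(0.975)
        denom = 1 + z**2 / n
        centre = (pred + z**2 / (2 * n)) / denom
        half = (z / denom) * np.sqrt(pred * (1 - pred) / n + z**2 / (4 * n**2))
        return np.clip(centre - half, 0, 1), np.clip(centre + half, 0, 1)

    def classify(self) -> pd.DataFrame:
        """Per-taxon table: abundance, observed/predicted occupancy, 95%
        bounds, and classification {above, within, below}."""
        recs = self.model.records
        p = np.array([r.mean_relative_abundance for r in recs])
        occ = np.array([r.occupancy for r in recs])
        valid = (p > 0) & (p < 1)
        pred = np.full(len(recs), np.nan)
        pred[valid] = self.predict(p[valid])
        lower = np.full(len(recs), np.nan)
        upper = np.full(len(recs), np.nan)
        if valid.any():
            lower[valid], upper[valid] = self.envelope(p[valid])
        cls = np.where(
            ~valid, "unclassified", np.where(occ > upper, "above", np.where(occ < lower, "below", "within"))
        )
        return pd.DataFrame(
            {
                "asv_id": [r.asv_id for r in recs],
                "mean_relative_abundance": p,
                "observed_occupancy": occ,
                "predicted_occupancy": pred,
                "lower95": lower,
                "upper95": upper,
                "classification": cls,
            }
        )

    def summary(self) -> str:
        counts = self.classify()["classification"].value_counts()
        lines = [
            "Sloan neutral community model (least squares on occupancy)",
            "----------------------------------------------------------",
            f"migration parameter m : {self.m:.6g}",
            f"effective depth N     : {self.N:g} reads",
            f"detection limit d     : {self.d:g} reads",
            f"R-squared             : {self.r_squared:.4f}",
            f"taxa fitted           : {int(self.model._fit_mask.sum())}",
            f"above envelope        : {int(counts.get('above', 0))}",
            f"within envelope       : {int(counts.get('within', 0))}",
            f"below envelope        : {int(counts.get('below', 0))}",
        ]
        return "\n".join(lines)


def fit_neutral(
    records: Sequence[OccupancyAbundanceRecord],
    N: float,
    d: float = 1.0,
    n_samples: int | None = None,
) -> NeutralFitResults:
    """Convenience wrapper: build the model and fit in one call."""
    return NeutralCommunityModel(records, N=N, d=d, n_samples=n_samples).fit()
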