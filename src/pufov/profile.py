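"""Eccentricity-dependent perception profiles and group comparisons.

Mean or maximum saccade amplitudes compress the peripheral detection field
into a single number; a more informative description is the full detection
probability as a function of eccentricity.  This module fits, per change
type, the Gaussian profile

    p(e) = A * exp(-e^2 / (2 * sigma^2)),

centered at 0 deg eccentricity, to binned event outcomes: events (detected
or not) are binned by their eccentricity at onset/detection, each bin
contributes detected/total, and the curve is fitted by least squares
weighted by the bin totals.  ``A`` is the detection probability at the point
of gaze and ``sigma`` the angular width of the perceptive field; the pUFOV
of a change type is characterised by the pair (A, sigma).

The module follows the usual model/results split: build a
:class:`PerceptionProfileModel` from data, call :meth:`~PerceptionProfileModel.fit`,
and read estimates, uncertainties and diagnostics off the returned
:class:`PerceptionProfileFit`.

One-way fixed-effects ANOVA comparisons between change types (reaction
times, detection ratios, amplitudes) are provided by :func:`anova_oneway`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .stimulus import CHANGE_TYPES

__all__ = [
    "PerceptionProfileModel",
    "PerceptionProfileFit",
    "FitError",
    "AnovaResult",
    "anova_oneway",
    "anova_by_type",
    "TYPE_LETTER",
]

TYPE_LETTER = {"color": "C", "shape": "S", "motion": "M"}


class FitError(RuntimeError):
    """Raised when a perception profile cannot be estimated from the data."""


def _gauss(e, amplitude, sigma):
    return amplitude * np.exp(-(np.asarray(e, dtype=float) ** 2) / (2.0 * sigma**2))


class PerceptionProfileModel:
    """Binned Gaussian model of detection probability over eccentricity.

    Parameters
    ----------
    detected : array-like of bool
        Per-event detection indicator.  Every event, detected or not, must be
        present: the per-bin probability is detected/total.
    eccentricity_deg : array-like of float
        Per-event eccentricity (angular distance of the changing feature from
        the gaze direction), degrees.
    change_type : str, optional
        Label carried through to the results.
    bin_width_deg : float
        Eccentricity bin width; 5 deg by default.
    free_center : bool
        If True the Gaussian center is a third free parameter; by default it
        is fixed at 0 deg (the profile is assumed symmetric around the point
        of gaze).
    """

    def __init__(
        self,
        detected,
        eccentricity_deg,
        change_type: str | None = None,
        bin_width_deg: float = 5.0,
        free_center: bool = False,
    ):
        detected = np.asarray(detected, dtype=bool)
        ecc = np.asarray(eccentricity_deg, dtype=float)
        if detected.shape != ecc.shape or detected.ndim != 1:
            raise ValueError("detected and eccentricity_deg must be equal-length 1-D")
        keep = np.isfinite(ecc)
        self.detected = detected[keep]
        self.eccentricity_deg = ecc[keep]
        self.change_type = change_type
        if bin_width_deg <= 0:
            raise ValueError("bin_width_deg must be positive")
        self.bin_width_deg = float(bin_width_deg)
        self.free_center = bool(free_center)

    @classmethod
    def from_outcomes(
        cls,
        outcomes: pd.DataFrame,
        change_type: str,
        bin_width_deg: float = 5.0,
        free_center: bool = False,
        ecc_source: str = "onset",
    ) -> "PerceptionProfileModel":
        """Build the model from a pipeline outcome table.

        With ``ecc_source="onset"`` (default) every event — detected or not —
        contributes its aligned-gaze eccentricity at event onset, so numerator
        and denominator of each bin share one measurement.  With
        ``ecc_source="saccade"`` detected events instead contribute the
        amplitude of the saccade that reached the feature (the classical
        proxy for the eccentricity of perception), falling back to the onset
        eccentricity when no such saccade was resolved.
        """
        sub = outcomes[outcomes["change_type"] == change_type]
        if len(sub) == 0:
            raise FitError(f"no events of type {change_type!r}")
        if ecc_source == "onset":
            ecc = sub["ecc_onset_deg"].to_numpy()
        elif ecc_source == "saccade":
            ecc = np.where(
                sub["detected"] & np.isfinite(sub["ecc_detection_deg"]),
                sub["ecc_detection_deg"],
                sub["ecc_onset_deg"],
            )
        else:
            raise ValueError("ecc_source must be 'onset' or 'saccade'")
        return cls(
            detected=sub["detected"].to_numpy(),
            eccentricity_deg=ecc,
            change_type=change_type,
            bin_width_deg=bin_width_deg,
            free_center=free_center,
        )

    def bin_counts(self) -> pd.DataFrame:
        """Per-bin detected and total counts."""
        w = self.bin_width_deg
        hi = max(self.eccentricity_deg.max() if len(self.eccentricity_deg) else w, w)
        edges = np.arange(0.0, hi + w, w)
        idx = np.clip(np.digitize(self.eccentricity_deg, edges) - 1, 0, len(edges) - 2)
        total = np.bincount(idx, minlength=len(edges) - 1)
        det = np.bincount(idx, weights=self.detected.astype(float), minlength=len(edges) - 1)
        return pd.DataFrame(
            {
                "bin_lo_deg": edges[:-1],
                "bin_hi_deg": edges[1:],
                "center_deg": 0.5 * (edges[:-1] + edges[1:]),
                "detected": det.astype(int),
                "total": total,
            }
        )

    def fit(self) -> "PerceptionProfileFit":
        """Weighted least-squares fit of the Gaussian profile.

        Weights are the per-bin totals.  ``A`` is box-constrained to [0, 1]
        and ``sigma`` to positive values.  Raises :class:`FitError` when no
        event was detected or fewer than three bins contain events.
        """
        bins = self.bin_counts()
        info = bins[bins["total"] > 0]
        if int(info["detected"].sum()) == 0:
            raise FitError("no detected events; profile amplitude is unidentified")
        if len(info) < 3:
            raise FitError(f"only {len(info)} informative bins; need at least 3")
        x = info["center_deg"].to_numpy(dtype=float)
        n = info["total"].to_numpy(dtype=float)
        p = info["detected"].to_numpy(dtype=float) / n

        mass = np.sum(n * p)
        sigma0 = float(np.sqrt(np.sum(n * p * x**2) / mass)) if mass > 0 else x.max() / 2
        sigma0 = min(max(sigma0, self.bin_width_deg / 4), 10 * x.max())
        a0 = float(np.clip(p.max(), 1e-3, 1.0))

        if self.free_center:
            f = lambda e, a, s, c: a * np.exp(-((e - c) ** 2) / (2.0 * s**2))
            p0 = [a0, sigma0, 0.0]
            lo, hi = [0.0, 1e-6, -90.0], [1.0, np.inf, 90.0]
        else:
            f = _gauss
            p0 = [a0, sigma0]
            lo, hi = [0.0, 1e-6], [1.0, np.inf]
        try:
            popt, pcov = optimize.curve_fit(
                f,
                x,
                p,
                p0=p0,
                sigma=1.0 / np.sqrt(n),
                absolute_sigma=False,
                bounds=(lo, hi),
                maxfev=20000,
            )
        except RuntimeError as exc:
            raise FitError(f"profile fit did not converge: {exc}") from exc
        resid = p - f(x, *popt)
        rss = float(np.sum(n * resid**2))
        return PerceptionProfileFit(
            model=self,
            params=np.asarray(popt, dtype=float),
            cov_params=np.asarray(pcov, dtype=float),
            rss=rss,
            bins=bins,
        )


@dataclass
class PerceptionProfileFit:
    """Results of a perception-profile fit."""

    model: PerceptionProfileModel
    params: np.ndarray  # (A, sigma[, center])
    cov_params: np.ndarray
    rss: float
    bins: pd.DataFrame

    @property
    def amplitude(self) -> float:
        return float(self.params[0])

    @property
    def sigma_deg(self) -> float:
        return float(self.params[1])

    @property
    def center_deg(self) -> float:
        return float(self.params[2]) if len(self.params) > 2 else 0.0

    @property
    def bse(self) -> np.ndarray:
        """Approximate standard errors of (A, sigma[, center])."""
        return np.sqrt(np.clip(np.diag(self.cov_params), 0.0, None))

    def predict(self, eccentricity_deg):
        """Detection probability predicted at the given eccentricities."""
        e = np.asarray(eccentricity_deg, dtype=float) - self.center_deg
        return _gauss(e, self.amplitude, self.sigma_deg)

    def to_dict(self) -> dict:
        return {
            "change_type": self.model.change_type,
            "amplitude": self.amplitude,
            "sigma_deg": self.sigma_deg,
            "center_deg": self.center_deg,
            "bse": self.bse.tolist(),
            "rss": self.rss,
            "n_events": int(self.bins["total"].sum()),
            "n_bins": int((self.bins["total"] > 0).sum()),
            "bin_width_deg": self.model.bin_width_deg,
        }

    def summary(self) -> str:
        b = self.bse
        lines = [
            "Perception profile fit (Gaussian over eccentricity)",
            "=" * 51,
            f"change type:        {self.model.change_type or '-'}",
            f"events (bins):      {int(self.bins['total'].sum())} "
            f"({int((self.bins['total'] > 0).sum())} informative)",
            f"bin width:          {self.model.bin_width_deg:.1f} deg",
            f"amplitude A:        {self.amplitude:.4f}  (se {b[0]:.4f})",
            f"width sigma:        {self.sigma_deg:.2f} deg  (se {b[1]:.2f})",
        ]
        if len(self.params) > 2:
            lines.append(f"center:             {self.center_deg:.2f} deg  (se {b[2]:.2f})")
        lines.append(f"weighted RSS:       {self.rss:.4f}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot binned detection probabilities and the fitted curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        info = self.bins[self.bins["total"] > 0]
        ax.scatter(
            info["center_deg"],
            info["detected"] / info["total"],
            s=10 + 90 * info["total"] / info["total"].max(),
            alpha=0.6,
            label="binned detection rate",
        )
        e = np.linspace(0, float(self.bins["bin_hi_deg"].max()), 200)
        ax.plot(e, self.predict(e), color="C3", label="Gaussian fit")
        ax.set_xlabel("eccentricity (deg)")
        ax.set_ylabel("detection probability")
        ax.set_ylim(0, 1.05)
        if self.model.change_type:
            ax.set_title(f"{self.model.change_type}: A={self.amplitude:.2f}, "
                         f"sigma={self.sigma_deg:.1f} deg")
        ax.legend()
        return ax


# ---------------------------------------------------------------------------
# one-way ANOVA


@dataclass(frozen=True)
class AnovaResult:
    label: str
    f_stat: float
    p_value: float
    group_sizes: tuple[int, ...]

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "F": self.f_stat,
            "p": self.p_value,
            "group_sizes": list(self.group_sizes),
        }


def anova_oneway(groups: list, label: str = "") -> AnovaResult:
    """Classical one-way fixed-effects ANOVA.

    ``groups`` is a list of 1-D samples (e.g. per-participant means, one
    group per change type).  Degenerate input with zero variance everywhere
    and equal group means yields F = 0, p = 1; zero within-group variance
    with unequal means yields F = inf, p = 0.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2 or any(len(a) < 2 for a in arrs):
        raise ValueError("need at least two groups with at least two values each")
    grand = np.concatenate(arrs)
    within = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrs)
    between = sum(len(a) * float((a.mean() - grand.mean()) ** 2) for a in arrs)
    if within == 0.0:
        if between <= 1e-300:
            return AnovaResult(label, 0.0, 1.0, tuple(len(a) for a in arrs))
        return AnovaResult(label, np.inf, 0.0, tuple(len(a) for a in arrs))
    f, p = stats.f_oneway(*arrs)
    return AnovaResult(label, float(f), float(p), tuple(len(a) for a in arrs))


def anova_by_type(values_by_type: dict[str, np.ndarray]) -> list[AnovaResult]:
    """Pairwise and omnibus comparisons between the three change types.

    Produces the labels C-S, S-M, C-M and C-S-M for one per-participant
    metric (reaction time, detection ratio, or amplitude).
    """
    order = [t for t in CHANGE_TYPES if t in values_by_type]
    results = []
    pairs = [("color", "shape"), ("shape", "motion"), ("color", "motion")]
    for a, b in pairs:
        if a in values_by_type and b in values_by_type:
            results.append(
                anova_oneway(
                    [values_by_type[a], values_by_type[b]],
                    label=f"{TYPE_LETTER[a]}-{TYPE_LETTER[b]}",
                )
            )
    if len(order) >= 3:
        results.append(
            anova_oneway(
                [values_by_type[t] for t in order],
                label="-".join(TYPE_LETTER[t] for t in order),
            )
        )
    return results
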