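"""LMS (Box-Cox power / median / coefficient-of-variation) growth references.

A growth reference chart tabulates, for each sex and age (or length),
the triple (L, M, S) of the Cole LMS parameterization.  A measurement
``x`` is converted to a z-score by

    z = ((x / M)**L - 1) / (L * S)      if L != 0
    z = ln(x / M) / S                   if L == 0

which is continuous in L at L = 0.  Charts are stored long-form
(measure, source, sex, axis_value, L, M, S) and interpolated linearly
in the axis variable within sex; lookups outside the tabulated axis
range raise :class:`ChartRangeError` rather than extrapolating.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MEASURES = ("height_for_age", "weight_for_age", "bmi_for_age", "weight_for_length")
CHART_COLUMNS = ["measure", "source", "sex", "axis_value", "L", "M", "S"]


class InvalidMeasurementError(ValueError):
    """A measurement or LMS parameter outside its support (x, M, S must be > 0)."""


class ChartRangeError(LookupError):
    """A lookup age/length outside the tabulated axis range of a chart."""


def lms_zscore(x, L, M, S):
    """Convert a positive measurement to an LMS z-score.

    Parameters may be scalars or broadcastable arrays.  Uses the
    ``expm1`` form of the Box-Cox transform so the L -> 0 limit is
    numerically smooth.
    """
    x = np.asarray(x, dtype=float)
    L = np.asarray(L, dtype=float)
    M = np.asarray(M, dtype=float)
    S = np.asarray(S, dtype=float)
    if np.any(x <= 0) or np.any(M <= 0) or np.any(S <= 0):
        raise InvalidMeasurementError("x, M and S must all be positive")
    logratio = np.log(x / M)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(L == 0.0, logratio / S, np.expm1(L * logratio) / (np.where(L == 0.0, 1.0, L) * S))
    if z.ndim == 0:
        return float(z)
    return z


def lms_inverse(z, L, M, S):
    """Invert the LMS transform: the measurement whose z-score is ``z``.

    Raises :class:`InvalidMeasurementError` when the requested z lies
    outside the support of the Box-Cox transform (1 + L*S*z <= 0).
    """
    z = np.asarray(z, dtype=float)
    L = np.asarray(L, dtype=float)
    M = np.asarray(M, dtype=float)
    S = np.asarray(S, dtype=float)
    if np.any(M <= 0) or np.any(S <= 0):
        raise InvalidMeasurementError("M and S must be positive")
    inner = 1.0 + L * S * z
    if np.any((L != 0.0) & (inner <= 0.0)):
        raise InvalidMeasurementError("z outside the support of the Box-Cox transform")
    with np.errstate(divide="ignore", invalid="ignore"):
        x = np.where(
            L == 0.0,
            M * np.exp(S * z),
            M * np.exp(np.log1p(L * S * z) / np.where(L == 0.0, 1.0, L)),
        )
    if x.ndim == 0:
        return float(x)
    return x


@dataclass
class ReferenceChart:
    """One measure/source chart: LMS triples by sex along an age (or length) axis.

    ``frame`` has columns sex, axis_value, L, M, S with the axis strictly
    increasing within sex.  The axis is age in years for the *_for_age
    measures and recumbent length in cm for weight_for_length; for
    preterm-role charts the axis is postmenstrual age in years.
    """

    measure: str
    source: str
    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}")
        f = self.frame
        if f[["L", "M", "S"]].isna().any().any():
            raise ValueError("chart contains missing L/M/S values")
        if (f["M"] <= 0).any() or (f["S"] <= 0).any():
            raise ValueError("chart M and S must be positive")
        for sex, grp in f.groupby("sex"):
            ax = grp["axis_value"].to_numpy()
            if not np.all(np.diff(ax) > 0):
                raise ValueError(f"chart axis not strictly increasing for sex={sex!r}")
        self._by_sex = {sex: grp.sort_values("axis_value") for sex, grp in f.groupby("sex")}

    def axis_range(self, sex: str) -> tuple[float, float]:
        ax = self._by_sex[sex]["axis_value"]
        return float(ax.iloc[0]), float(ax.iloc[-1])

    def lms_at(self, sex: str, axis_value: float) -> tuple[float, float, float]:
        """Linearly interpolated (L, M, S) at ``axis_value``; no extrapolation."""
        try:
            grp = self._by_sex[sex]
        except KeyError:
            raise ChartRangeError(f"{self.measure}/{self.source}: no rows for sex={sex!r}") from None
        ax = grp["axis_value"].to_numpy()
        if axis_value < ax[0] or axis_value > ax[-1]:
            raise ChartRangeError(
                f"{self.measure}/{self.source}/{sex}: {axis_value:.4g} outside [{ax[0]:.4g}, {ax[-1]:.4g}]"
            )
        L = float(np.interp(axis_value, ax, grp["L"].to_numpy()))
        M = float(np.interp(axis_value, ax, grp["M"].to_numpy()))
        S = float(np.interp(axis_value, ax, grp["S"].to_numpy()))
        return L, M, S

    def zscore(self, x: float, sex: str, axis_value: float) -> float:
        return float(lms_zscore(x, *self.lms_at(sex, axis_value)))

    def inverse(self, z: float, sex: str, axis_value: float) -> float:
        L, M, S = self.lms_at(sex, axis_value)
        return float(lms_inverse(z, L, M, S))


class ChartSet:
    """A collection of reference charts keyed by (measure, source)."""

    def __init__(self, charts: dict[tuple[str, str], ReferenceChart]):
        self._charts = dict(charts)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ChartSet":
        missing = set(CHART_COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"chart table missing columns: {sorted(missing)}")
        charts = {}
        for (measure, source), grp in frame.groupby(["measure", "source"]):
            body = grp[["sex", "axis_value", "L", "M", "S"]].reset_index(drop=True)
            charts[(measure, source)] = ReferenceChart(measure, source, body)
        return cls(charts)

    @classmethod
    def from_csv(cls, path) -> "ChartSet":
        return cls.from_frame(pd.read_csv(path))

    def to_frame(self) -> pd.DataFrame:
        parts = []
        for (measure, source), chart in sorted(self._charts.items()):
            f = chart.frame.copy()
            f.insert(0, "source", source)
            f.insert(0, "measure", measure)
            parts.append(f[CHART_COLUMNS])
        return pd.concat(parts, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def sources(self) -> set[str]:
        return {source for _, source in self._charts}

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._charts

    def get(self, measure: str, source: str) -> ReferenceChart:
        try:
            return self._charts[(measure, source)]
        except KeyError:
            raise ChartRangeError(f"no chart for measure={measure!r}, source={source!r}") from None
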