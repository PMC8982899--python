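"""Growth-rate inhibition (GR) metrics and ZIP synergy scoring.

GR value: the normalized growth-rate ratio

    GR(c, t) = 2 ** ( k(c, t) / k(0) ) - 1

with k(c, t) the exponential growth rate of treated cells and k(0) the
untreated control rate; GR = 1 means no effect, 0 full cytostasis, negative
values cell killing (bounded below by -1).  GRmax is the minimum GR over the
tested concentrations (the maximal drug effect).

Combination 6x6 dose-response matrices (fractional inhibition in [0, 1],
zero-concentration margins encoding the monotherapies) are summarized with a
zero-interaction-potency (ZIP) style delta: per interior cell, observed
inhibition minus the independence (Bliss) expectation y1 + y2 - y1*y2 of the
monotherapy effects; the summary score is the mean interior delta in
percentage points, with scores above 5 called synergistic.  By default the
monotherapy effects are taken from the observed margins; ``smooth_margins``
replaces them with four-parameter logistic fits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

logger = logging.getLogger("omu_synergy")

ZIP_SYNERGY_THRESHOLD = 5.0  # percentage points


def gr_value(k_ct: float, k0: float) -> float:
    """Normalized growth-rate inhibition 2**(k_ct/k0) - 1; requires k0 > 0."""
    if k0 <= 0:
        raise ValueError("control growth rate k0 must be positive")
    return float(2.0 ** (k_ct / k0) - 1.0)


@dataclass
class GRCurve:
    drug_id: str
    concentrations: np.ndarray
    gr_values: np.ndarray

    @property
    def gr_max(self) -> float:
        """Maximal drug effect: the minimum GR over tested concentrations."""
        return float(np.min(self.gr_values))


def gr_curve(
    drug_id: str,
    concentrations: np.ndarray,
    treated_counts: np.ndarray,
    control_count_t: float,
    initial_count: float,
    t: float = 72.0,
) -> GRCurve:
    """GR curve from endpoint cell counts.

    Growth rates come from exponential fits between two timepoints:
    k = ln(x(t) / x(0)) / t, with t in hours (72 h assay by default).
    ``treated_counts`` holds the endpoint count per concentration,
    ``control_count_t`` the untreated endpoint and ``initial_count`` the
    common seeding count.
    """
    concentrations = np.asarray(concentrations, dtype=float)
    treated_counts = np.asarray(treated_counts, dtype=float)
    if (treated_counts <= 0).any() or control_count_t <= 0 or initial_count <= 0:
        raise ValueError("cell counts must be positive")
    k0 = np.log(control_count_t / initial_count) / t
    if k0 <= 0:
        raise ValueError("control must grow (k0 > 0)")
    k_ct = np.log(treated_counts / initial_count) / t
    grs = np.asarray([gr_value(k, k0) for k in k_ct])
    return GRCurve(drug_id=drug_id, concentrations=concentrations, gr_values=grs)


# ---------------------------------------------------------------------------
# four-parameter logistic


def four_pl(dose, lo, hi, ec50, slope):
    """Rising 4PL inhibition curve: lo at dose 0, hi at saturating dose."""
    dose = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(dose > 0, ec50 / dose, np.inf)
    return lo + (hi - lo) / (1.0 + ratio**slope)


@dataclass
class HillFit:
    lo: float
    hi: float
    ec50: float
    slope: float
    converged: bool
    degenerate: bool = False
    interp: tuple[np.ndarray, np.ndarray] | None = None  # fallback table

    def __call__(self, dose):
        if self.interp is not None:
            return np.interp(dose, *self.interp)
        return four_pl(dose, self.lo, self.hi, self.ec50, self.slope)


def fit_hill(doses: np.ndarray, responses: np.ndarray) -> HillFit:
    """Bounded least-squares 4PL fit of inhibition vs dose.

    Bounds: lo, hi in [0, 1]; EC50 within the positive dose range times
    [0.01, 100]; slope in (0, 10].  A constant response is flagged degenerate;
    non-convergence falls back to a monotone step interpolation (flagged).
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    pos = doses > 0
    if pos.sum() < 3 or len(doses) < 4:
        raise ValueError("need at least 4 dose points (3 positive) for a 4PL fit")
    if np.ptp(responses) < 1e-12:
        level = float(np.clip(responses[0], 0.0, 1.0))
        logger.warning("fit_hill: constant response; degenerate fit")
        return HillFit(lo=level, hi=level, ec50=float(np.median(doses[pos])),
                       slope=1.0, converged=True, degenerate=True)
    dmin, dmax = doses[pos].min(), doses[pos].max()
    p0 = [
        float(np.clip(responses[np.argmin(doses)], 0, 1)),
        float(np.clip(responses[np.argmax(doses)], 0, 1)),
        float(np.sqrt(dmin * dmax)),
        1.0,
    ]
    bounds = ([0.0, 0.0, dmin * 0.01, 1e-6], [1.0, 1.0, dmax * 100.0, 10.0])
    p0 = [min(max(p, lo), hi) for p, lo, hi in zip(p0, *bounds)]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                four_pl, doses, responses, p0=p0, bounds=bounds, maxfev=20000,
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        return HillFit(*[float(p) for p in popt], converged=True)
    except RuntimeError:
        logger.warning("fit_hill: no convergence; monotone interpolation fallback")
        order = np.argsort(doses)
        mono = np.maximum.accumulate(responses[order])
        return HillFit(lo=float(mono[0]), hi=float(mono[-1]),
                       ec50=float(np.sqrt(dmin * dmax)), slope=1.0,
                       converged=False, interp=(doses[order], mono))


# ---------------------------------------------------------------------------
# ZIP synergy


@dataclass
class DoseResponseMatrix:
    """6x6 combination grid of fractional inhibition with zero-dose margins."""

    drug1: str
    drug2: str
    conc1: np.ndarray  # len 6, first entry 0, strictly increasing
    conc2: np.ndarray
    responses: np.ndarray  # shape (6, 6); [i, j] at (conc1[i], conc2[j])
    n_clipped: int = 0

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "DoseResponseMatrix":
        """Build from a long-format table (drug1, conc1, drug2, conc2, response)."""
        drugs1 = df["drug1"].unique()
        drugs2 = df["drug2"].unique()
        if len(drugs1) != 1 or len(drugs2) != 1:
            raise ValueError("long table must describe a single drug pair")
        c1 = np.sort(df["conc1"].unique())
        c2 = np.sort(df["conc2"].unique())
        grid = df.pivot_table(index="conc1", columns="conc2", values="response")
        if grid.isna().any().any():
            raise ValueError("incomplete dose grid")
        resp = grid.loc[c1, c2].to_numpy(dtype=float)
        clipped = int(((resp < 0) | (resp > 1)).sum())
        if clipped:
            logger.warning("dose-response matrix %s/%s: clipped %d response(s) to [0, 1]",
                           drugs1[0], drugs2[0], clipped)
        return cls(
            drug1=str(drugs1[0]), drug2=str(drugs2[0]),
            conc1=c1, conc2=c2, responses=np.clip(resp, 0.0, 1.0),
            n_clipped=clipped,
        )

    def to_long(self) -> pd.DataFrame:
        rows = [
            {"drug1": self.drug1, "conc1": c1, "drug2": self.drug2,
             "conc2": c2, "response": self.responses[i, j]}
            for i, c1 in enumerate(self.conc1)
            for j, c2 in enumerate(self.conc2)
        ]
        return pd.DataFrame(rows)

    def __post_init__(self) -> None:
        self.conc1 = np.asarray(self.conc1, dtype=float)
        self.conc2 = np.asarray(self.conc2, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.responses.shape != (len(self.conc1), len(self.conc2)):
            raise ValueError("response grid shape does not match concentration axes")
        if (np.diff(self.conc1) <= 0).any() or (np.diff(self.conc2) <= 0).any():
            raise ValueError("concentration axes must be strictly increasing")
        if self.conc1[0] != 0 or self.conc2[0] != 0:
            raise ValueError("missing zero-concentration margin (monotherapy rows)")


@dataclass
class SynergyResult:
    drug1: str
    drug2: str
    zip_score: float  # percentage points
    synergy_call: bool
    delta_matrix: np.ndarray | None = None


def zip_synergy(
    m: DoseResponseMatrix,
    threshold: float = ZIP_SYNERGY_THRESHOLD,
    smooth_margins: bool = False,
) -> SynergyResult:
    """ZIP delta summary of a combination matrix.

    Per interior cell: delta = observed - (y1 + y2 - y1*y2) with y1, y2 the
    monotherapy inhibitions at the cell's concentrations, read from the
    zero-dose margins (or from 4PL fits to the margins with
    ``smooth_margins=True``).  zip_score is the mean interior delta x 100;
    scores above ``threshold`` percentage points are called synergistic.
    """
    y1 = m.responses[1:, 0]  # drug1 monotherapy at conc1[1:]
    y2 = m.responses[0, 1:]  # drug2 monotherapy at conc2[1:]
    if smooth_margins:
        f1 = fit_hill(m.conc1, m.responses[:, 0])
        f2 = fit_hill(m.conc2, m.responses[0, :])
        y1 = f1(m.conc1[1:])
        y2 = f2(m.conc2[1:])
    expected = y1[:, None] + y2[None, :] - y1[:, None] * y2[None, :]
    delta = m.responses[1:, 1:] - expected
    score = float(delta.mean() * 100.0)
    return SynergyResult(
        drug1=m.drug1, drug2=m.drug2, zip_score=score,
        synergy_call=bool(score > threshold), delta_matrix=delta,
    )
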