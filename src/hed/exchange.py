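"""Amide-exchange and heteronuclear-NOE dynamics analysis.

Three per-residue experiments are covered:

**H/D exchange protection.**  After transfer to D₂O, amide signals vanish
as protons exchange for deuterons; a residue still visible at late
timepoints is protected (hydrogen-bonded or buried).  Residues are classed
by the latest timepoint at which their signal is identifiable.

**Fast hydrogen exchange (water saturation transfer).**  During a
relaxation delay d the amide proton magnetization recovers by longitudinal
relaxation (rate R1) and by exchange with water protons (rate kex).  With
two-site Bloch–McConnell kinetics, starting from zero amide magnetization
and treating the water magnetization as a level w (normalized to
equilibrium; 0 under water saturation, the measured water fraction
otherwise), the observed intensity is

    I(d) = I_eq * (R1 + kex * w) / (R1 + kex) * (1 - exp(-(R1 + kex) d))

:func:`hetex_intensity` is the single point of truth for this forward
model: the synthetic generator and the fitter both call it.  Fitting the
saturated/unsaturated intensity pairs at several delays by bounded
nonlinear least squares yields (kex, R1, I_eq); the experiment is sensitive
in the window 0.1 s⁻¹ < kex < 10 s⁻¹.

**Heteronuclear NOE.**  noe = I_irradiated / I_unirradiated; negative
values mark picosecond–nanosecond flexible residues, values above 0.5
rigid ones.  OH-relayed NOE artifacts make amides next to Ser/Thr read
fast, so a flag column marks residues adjacent (i±1) to Ser/Thr for
optional exclusion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import FitError, ValidationError
from .io import IntensityTable

logger = logging.getLogger(__name__)

#: relaxation delays used by the reference experiments, s
DEFAULT_DELAYS = (0.566, 0.878, 1.659)

#: sensitivity window of the saturation-transfer experiment, s^-1
KEX_WINDOW = (0.1, 10.0)

#: default H/D observation timepoint grid, minutes
DEFAULT_TIMEPOINTS = (11.0, 39.0, 67.0, 431.0)

NOE_THRESHOLDS = (0.0, 0.5)


# ---------------------------------------------------------------------------
# H/D exchange protection


def hd_protection(observations: Mapping[tuple[str, int], Iterable[float]],
                  timepoints: Sequence[float] = DEFAULT_TIMEPOINTS
                  ) -> pd.DataFrame:
    """Classify residues by the latest timepoint their amide is identifiable.

    ``observations`` maps (chain, residue) to the set of timepoints
    (minutes) at which the signal was seen.  Sets should be prefix-closed
    in time (a signal seen late was seen early); violations are flagged,
    and the residue is classified by its latest observation.  Residues
    absent at the first timepoint class as fast exchangers.

    Output columns: ``chain residue last_seen protection prefix_closed``.
    """
    grid = sorted(timepoints)
    rows = []
    for (chain, residue), seen in sorted(observations.items()):
        seen = set(float(t) for t in seen)
        stray = seen - set(grid)
        if stray:
            raise ValidationError(
                f"residue {chain}{residue}: timepoints {sorted(stray)} not on "
                f"the shared grid {grid}"
            )
        last = max(seen) if seen else None
        expected = {t for t in grid if last is not None and t <= last}
        closed = seen == expected
        if not closed:
            logger.warning("residue %s%d: observations %s are not "
                           "prefix-closed in time", chain, residue, sorted(seen))
        if last is None:
            label = f"fast (<{grid[0]:g} min)"
        else:
            label = f">={last:g} min"
        rows.append({"chain": chain, "residue": residue,
                     "last_seen": last if last is not None else np.nan,
                     "protection": label, "prefix_closed": closed})
    return pd.DataFrame(rows)


def protection_classes(profile: pd.DataFrame) -> dict[str, list[tuple[str, int]]]:
    """Per-class residue lists from an hd_protection profile."""
    out: dict[str, list[tuple[str, int]]] = {}
    for _, row in profile.iterrows():
        out.setdefault(row["protection"], []).append((row["chain"], row["residue"]))
    return out


# ---------------------------------------------------------------------------
# fast exchange forward model and fit


def hetex_intensity(delay, kex: float, r1: float, i_eq: float,
                    water: float = 1.0, saturated: bool = False):
    """Forward saturation-transfer model; see module docstring.

    The single point of truth shared by :func:`fit_kex` and the synthetic
    generator.  ``water`` is the normalized water magnetization during the
    delay; under water saturation it is forced to zero.
    """
    if r1 <= 0:
        raise ValidationError("r1 must be > 0")
    if kex < 0:
        raise ValidationError("kex must be >= 0")
    delay = np.asarray(delay, float)
    w = 0.0 if saturated else water
    rate = r1 + kex
    return i_eq * (r1 + kex * w) / rate * (1.0 - np.exp(-rate * delay))


@dataclass
class HetexFit:
    """Per-residue saturation-transfer fit result."""

    kex: float
    r1: float
    i_eq: float
    residual_ss: float
    in_window: bool
    converged: bool
    n_obs: int
    message: str = ""

    def __post_init__(self) -> None:
        if self.converged:
            assert self.kex >= 0 and self.r1 > 0 and self.residual_ss >= 0


_KEX_STARTS = (0.2, 1.0, 5.0)


def fit_kex(delays: Sequence[float],
            i_sat: Sequence[float],
            i_nosat: Sequence[float],
            water: Sequence[float] | float = 1.0) -> HetexFit:
    """Fit (kex, R1, I_eq) to saturated/unsaturated intensities.

    ``water`` gives the normalized water magnetization at each delay for
    the unsaturated condition.  Multi-start bounded least squares (kex
    starts 0.2, 1, 5 s⁻¹) guards against local minima.  Non-convergence is
    reported in the returned record, not raised.
    """
    delays = np.asarray(delays, float)
    i_sat = np.asarray(i_sat, float)
    i_nosat = np.asarray(i_nosat, float)
    if len(set(np.round(delays, 9))) < 2:
        raise FitError("need >= 2 distinct relaxation delays")
    if not (len(delays) == len(i_sat) == len(i_nosat)):
        raise FitError("delays and intensities must align")
    w = np.broadcast_to(np.asarray(water, float), delays.shape)

    scale = max(float(np.max(np.abs(i_nosat))), 1e-12)

    def residuals(theta):
        kex, r1, i_eq = theta
        model_sat = hetex_intensity(delays, kex, r1, i_eq, saturated=True)
        model_nosat = hetex_intensity(delays, kex, r1, i_eq, water=w)
        return np.concatenate([model_sat - i_sat, model_nosat - i_nosat]) / scale

    best = None
    for kex0 in _KEX_STARTS:
        try:
            res = least_squares(
                residuals, x0=[kex0, 1.5, scale],
                bounds=([0.0, 1e-3, 1e-9 * scale], [1e3, 50.0, 1e3 * scale]),
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception as exc:  # solver failure on one start is not fatal
            logger.warning("fit start kex=%g failed: %s", kex0, exc)
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return HetexFit(np.nan, np.nan, np.nan, np.nan, False, False,
                        2 * len(delays), "all starts failed")
    kex, r1, i_eq = best.x
    ss = float(2.0 * best.cost * scale ** 2)
    return HetexFit(
        kex=float(kex), r1=float(r1), i_eq=float(i_eq), residual_ss=ss,
        in_window=bool(KEX_WINDOW[0] < kex < KEX_WINDOW[1]),
        converged=bool(best.success), n_obs=2 * len(delays),
        message=best.message,
    )


def fit_kex_table(table: IntensityTable) -> pd.DataFrame:
    """Fit every residue of an intensity table; one row per residue."""
    rows = []
    for chain, residue in table.residues():
        sub = table.data[(table.data["chain"] == chain)
                         & (table.data["residue"] == residue)]
        wide = sub.pivot_table(index="delay", columns="condition",
                               values="intensity", aggfunc="first")
        if not {"saturated", "unsaturated"}.issubset(wide.columns):
            logger.warning("residue %s%d lacks one condition; skipped",
                           chain, residue)
            continue
        wide = wide.dropna()
        if len(wide) < 2:
            logger.warning("residue %s%d has < 2 complete delays; skipped",
                           chain, residue)
            continue
        delays = wide.index.to_numpy()
        water = np.array([table.water_fraction(d) for d in delays])
        fit = fit_kex(delays, wide["saturated"].to_numpy(),
                      wide["unsaturated"].to_numpy(), water)
        rows.append({"chain": chain, "residue": residue, "kex": fit.kex,
                     "r1": fit.r1, "i_eq": fit.i_eq,
                     "residual_ss": fit.residual_ss,
                     "in_window": fit.in_window, "converged": fit.converged})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# heteronuclear NOE


def het_noe(i_irr, i_unirr,
            chain=None, residue=None,
            resnames: Mapping[tuple[str, int], str] | None = None,
            thresholds: tuple[float, float] = NOE_THRESHOLDS) -> pd.DataFrame:
    """Heteronuclear NOE ratios and rigidity classes.

    noe = I_irradiated / I_unirradiated; class "flexible" below
    ``thresholds[0]``, "rigid" strictly above ``thresholds[1]`` and
    "intermediate" between (both thresholds inclusive on the intermediate
    side).  Records with zero unirradiated intensity are flagged undefined.
    If ``resnames`` is given, ``near_ser_thr`` marks residues adjacent
    (i±1, same chain) to Ser/Thr, whose ratios can be biased by OH-relayed
    exchange NOE.
    """
    i_irr = np.atleast_1d(np.asarray(i_irr, float))
    i_unirr = np.atleast_1d(np.asarray(i_unirr, float))
    n = len(i_irr)
    chain = np.atleast_1d(chain) if chain is not None else np.array(["A"] * n)
    residue = np.atleast_1d(residue) if residue is not None \
        else np.arange(1, n + 1)

    with np.errstate(divide="ignore", invalid="ignore"):
        noe = np.where(i_unirr != 0, i_irr / i_unirr, np.nan)
    undefined = i_unirr == 0
    if undefined.any():
        logger.warning("%d residues have zero unirradiated intensity",
                       int(undefined.sum()))
    lo, hi = thresholds
    cls = np.where(noe < lo, "flexible",
                   np.where(noe > hi, "rigid", "intermediate"))
    cls = np.where(np.isfinite(noe), cls, "undefined")

    out = pd.DataFrame({"chain": chain, "residue": residue,
                        "noe": noe, "class": cls})
    if resnames is not None:
        st = {(c, r) for (c, r), name in resnames.items()
              if name.upper() in ("SER", "THR")}
        out["near_ser_thr"] = [
            (c, r - 1) in st or (c, r + 1) in st
            for c, r in zip(out["chain"], out["residue"])
        ]
    return out


def classify_regions(classes: pd.DataFrame | pd.Series,
                     min_run: int = 3,
                     class_col: str = "class") -> pd.DataFrame:
    """Maximal same-class runs of consecutive residues, length >= min_run.

    Accepts a DataFrame with chain/residue/class columns (e.g. het_noe
    output) or a Series indexed by (chain, residue).  Returns columns
    ``chain start end class length``.
    """
    if isinstance(classes, pd.Series):
        df = classes.rename("class").reset_index()
        df.columns = ["chain", "residue", "class"]
        class_col = "class"
    else:
        df = classes
    df = df.sort_values(["chain", "residue"])
    rows = []
    current = None  # [chain, start, end, label]
    for _, r in df.iterrows():
        key = (r["chain"], int(r["residue"]), r[class_col])
        if current is not None and key[0] == current[0] \
                and key[1] == current[2] + 1 and key[2] == current[3]:
            current[2] = key[1]
        else:
            if current is not None:
                rows.append(current)
            current = [key[0], key[1], key[1], key[2]]
    if current is not None:
        rows.append(current)
    out = pd.DataFrame(rows, columns=["chain", "start", "end", "class"])
    out["length"] = out["end"] - out["start"] + 1
    return out[out["length"] >= min_run].reset_index(drop=True)
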