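"""Equilibrium and kinetic binding fits.

Two readouts are supported:

* Fluorescence polarization (FP) dose-response, fit to the one-site
  specific + total binding model
  ``mP(X) = Bmax * X / (Kd + X) + ns * X + background``.

* Bio-layer interferometry (BLI) sensorgrams, fit globally across all
  analyte concentrations and both phases with a 1:1 Langmuir model:
  association ``R(t) = Req * (1 - exp(-kobs * t))`` with
  ``Req = Rmax * C / (C + Kd)`` and ``kobs = kon * C + koff``;
  dissociation ``R(t) = R(t_d) * exp(-koff * (t - t_d))``.
  ``Kd = koff / kon`` holds as an exact identity in every fit.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from lmfit import Parameters, minimize
from lmfit.models import Model

# ---------------------------------------------------------------------------
# Fluorescence polarization
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class FPDataset:
    concentration: np.ndarray  # M
    polarization: np.ndarray   # mP
    replicate_id: str = "rep1"

    def __post_init__(self) -> None:
        self.concentration = np.asarray(self.concentration, float)
        self.polarization = np.asarray(self.polarization, float)
        if self.concentration.shape != self.polarization.shape:
            raise ValueError("paired vectors must have equal length")
        if np.any(self.concentration < 0):
            raise ValueError("concentrations must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"concentration_M": self.concentration,
                             "mP": self.polarization,
                             "replicate": self.replicate_id})


@dataclasses.dataclass
class FPFit:
    Kd: float            # M
    Bmax: float          # mP
    ns_slope: float      # mP per M
    background: float    # mP
    stderr: dict[str, float | None]
    r_squared: float
    success: bool
    message: str = ""


def fp_model(X: np.ndarray, Kd: float, Bmax: float, ns: float, bg: float) -> np.ndarray:
    """One-site specific + total binding: hyperbola + linear nonspecific."""
    return Bmax * X / (Kd + X) + ns * X + bg


def fit_fp(data: FPDataset | list[FPDataset],
           init: dict[str, float] | None = None) -> FPFit:
    """Nonlinear least-squares fit of the one-site total binding model.

    Multiple replicates are averaged per concentration before fitting.
    Standard errors come from the Jacobian at the optimum.
    """
    if isinstance(data, list):
        df = pd.concat([d.to_frame() for d in data])
        g = df.groupby("concentration_M")["mP"].mean()
        x = g.index.to_numpy()
        y = g.to_numpy()
    else:
        x, y = data.concentration, data.polarization
    if len(np.unique(x)) < 5:
        raise ValueError("need at least 5 distinct concentrations")

    init = init or {}
    span = y.max() - y.min()
    model = Model(fp_model, independent_vars=["X"])
    params = model.make_params(
        Kd=dict(value=init.get("Kd", np.median(x[x > 0])), min=1e-12),
        Bmax=dict(value=init.get("Bmax", span if span > 0 else 1.0), min=0),
        ns=dict(value=init.get("ns", 0.0)),
        bg=dict(value=init.get("bg", y.min())),
    )
    result = model.fit(y, params, X=x)
    ss_res = float(np.sum(result.residual ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    p = result.params
    return FPFit(
        Kd=p["Kd"].value, Bmax=p["Bmax"].value,
        ns_slope=p["ns"].value, background=p["bg"].value,
        stderr={k: p[k].stderr for k in ("Kd", "Bmax", "ns", "bg")},
        r_squared=r2, success=result.success,
        message=result.message)


# ---------------------------------------------------------------------------
# Bio-layer interferometry
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class Sensorgram:
    concentration: float   # M
    time: np.ndarray       # s
    response: np.ndarray   # nm

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, float)
        self.response = np.asarray(self.response, float)
        if self.time.shape != self.response.shape:
            raise ValueError("time/response length mismatch")


@dataclasses.dataclass
class BLIDataset:
    sensorgrams: list[Sensorgram]
    association_window: tuple[float, float]   # s
    dissociation_window: tuple[float, float]  # s

    def __post_init__(self) -> None:
        a0, a1 = self.association_window
        d0, d1 = self.dissociation_window
        if not (a0 < a1 <= d0 < d1):
            raise ValueError("association must precede dissociation, "
                             "windows non-overlapping")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sg in self.sensorgrams:
            phase = np.where(sg.time < self.dissociation_window[0],
                             "association", "dissociation")
            rows.append(pd.DataFrame({
                "concentration_M": sg.concentration, "time_s": sg.time,
                "response_nm": sg.response, "phase": phase}))
        return pd.concat(rows, ignore_index=True)


@dataclasses.dataclass
class BLIFit:
    kon: float     # 1/(M s)
    koff: float    # 1/s
    Rmax: float    # nm
    Kd: float      # M, = koff/kon exactly
    kobs: dict[float, float]   # per concentration, 1/s
    Req: dict[float, float]    # per concentration, nm
    chi_squared: float
    r_squared: float
    stderr: dict[str, float | None]
    success: bool


def _bli_curve(t: np.ndarray, conc: float, kon: float, koff: float,
               rmax: float, t_assoc_start: float, t_dissoc_start: float
               ) -> np.ndarray:
    kd = koff / kon
    req = rmax * conc / (conc + kd)
    kobs = kon * conc + koff
    ta = np.clip(t - t_assoc_start, 0.0, None)
    r_assoc = req * (1.0 - np.exp(-kobs * ta))
    r_at_td = req * (1.0 - np.exp(-kobs * (t_dissoc_start - t_assoc_start)))
    r = np.where(t < t_dissoc_start, r_assoc,
                 r_at_td * np.exp(-koff * (t - t_dissoc_start)))
    return r


def simulate_bli(params: tuple[float, float, float],
                 concentrations: np.ndarray,
                 association_window: tuple[float, float] = (0.0, 300.0),
                 dissociation_window: tuple[float, float] = (300.0, 600.0),
                 noise_sd: float = 0.0, seed: int = 0,
                 dt: float = 1.0) -> BLIDataset:
    """Forward 1:1 model sensorgrams with additive Gaussian noise."""
    kon, koff, rmax = params
    if min(kon, koff, rmax) <= 0:
        raise ValueError("kinetic parameters must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(association_window[0], dissociation_window[1] + dt / 2, dt)
    sgs = []
    for c in np.asarray(concentrations, float):
        r = _bli_curve(t, c, kon, koff, rmax,
                       association_window[0], dissociation_window[0])
        if noise_sd > 0:
            r = r + rng.normal(0.0, noise_sd, size=r.shape)
        sgs.append(Sensorgram(float(c), t.copy(), r))
    return BLIDataset(sgs, association_window, dissociation_window)


def align_sensorgrams(data: BLIDataset, baseline_window: float = 5.0) -> BLIDataset:
    """Zero each curve on the mean of the last seconds before association.

    Stands in for the instrument's interstep correction: points earlier
    than the association start define the baseline; if none exist the
    curve is left unchanged.
    """
    a0 = data.association_window[0]
    out = []
    for sg in data.sensorgrams:
        pre = sg.response[(sg.time >= a0 - baseline_window) & (sg.time < a0)]
        offset = float(pre.mean()) if len(pre) else 0.0
        out.append(Sensorgram(sg.concentration, sg.time, sg.response - offset))
    return BLIDataset(out, data.association_window, data.dissociation_window)


def fit_bli(data: BLIDataset,
            init: dict[str, float] | None = None) -> BLIFit:
    """Global 1:1 fit: one (kon, koff, Rmax) shared by all curves and phases.

    Parameter bounds (kon in [1e2, 1e8] /M/s, koff in [1e-6, 1] /s) are
    wide and prevent sign flips; optimization is least squares over every
    sampled point of every sensorgram.
    """
    if len(data.sensorgrams) < 4:
        raise ValueError("global fit needs at least 4 concentrations")
    init = init or {}
    rmax_guess = max(sg.response.max() for sg in data.sensorgrams)
    params = Parameters()
    params.add("kon", value=init.get("kon", 1e5), min=1e2, max=1e8)
    params.add("koff", value=init.get("koff", 1e-2), min=1e-6, max=1.0)
    params.add("rmax", value=init.get("Rmax", max(rmax_guess, 1e-3)), min=1e-6)

    a0 = data.association_window[0]
    d0 = data.dissociation_window[0]

    def residual(p: Parameters) -> np.ndarray:
        res = []
        for sg in data.sensorgrams:
            model = _bli_curve(sg.time, sg.concentration, p["kon"].value,
                               p["koff"].value, p["rmax"].value, a0, d0)
            res.append(sg.response - model)
        return np.concatenate(res)

    result = minimize(residual, params, method="leastsq")
    p = result.params
    kon, koff, rmax = p["kon"].value, p["koff"].value, p["rmax"].value
    kd = koff / kon
    all_y = np.concatenate([sg.response for sg in data.sensorgrams])
    ss_res = float(np.sum(result.residual ** 2))
    ss_tot = float(np.sum((all_y - all_y.mean()) ** 2))
    return BLIFit(
        kon=kon, koff=koff, Rmax=rmax, Kd=kd,
        kobs={sg.concentration: kon * sg.concentration + koff
              for sg in data.sensorgrams},
        Req={sg.concentration: rmax * sg.concentration / (sg.concentration + kd)
             for sg in data.sensorgrams},
        chi_squared=ss_res,
        r_squared=1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0,
        stderr={k: p[k].stderr for k in ("kon", "koff", "rmax")},
        success=result.success)
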