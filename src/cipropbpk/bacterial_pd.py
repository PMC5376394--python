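"""Bacterial growth and killing driven by unbound antibiotic concentration.

Each *E. coli* strain is represented by three states (CFU/ml):

* ``b_s`` — drug-susceptible, countable bacteria,
* ``b_r`` — a pre-existing less-susceptible subpopulation (higher EC50),
* ``b_f`` — filamentous, non-countable bacteria.

Countable bacteria grow at first-order rate ``k_growth`` capped by a shared
population ceiling and die naturally at ``k_death``. Drug-induced killing is
a saturable (Emax) function of the local unbound concentration,
``emax_kill * C^h / (EC50_eff^h + C^h)``, with the less-susceptible
subpopulation's EC50 inflated by a configurable factor. During a window of
length ``t_filament`` after first drug exposure, drug-induced "kill" flux is
diverted into the filamentous state instead of being removed — the cells are
still alive biomass but do not form colonies when plated; afterwards the
drug flux is true removal. Filaments do not divide and decay at ``k_death``
(plus any immune kill).

The neutrophil (immune) kill term is saturable in both the neutrophil count
and the bacterial burden:

    ``k_immune(B) = Kkill_ANC * ANC/(ANC + ANC50) * (1 - B/(B + B50))``

and applies identically to every bacterial state.

The population ceiling is parameterized so that the *stationary* total
bacterial concentration in a drug- and immune-free system equals ``b_max``:
the logistic bracket uses an internal capacity
``b_max * k_growth / (k_growth - k_death)``, which leaves the low-density net
growth rate at ``k_growth - k_death``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .config import default_strains_config

__all__ = [
    "StrainParameters",
    "PDParameters",
    "ImmuneParameters",
    "KillCurve",
    "drug_kill_rate",
    "immune_kill_rate",
    "simulate_killing",
    "default_strain_panel",
    "floor_for_log",
]


@dataclass(frozen=True)
class StrainParameters:
    """Drug-effect parameters for one strain.

    ``ec50`` defaults to ``mic`` scaled by the panel's MIC-to-EC50 factor;
    the less-susceptible subpopulation uses ``ec50 * resistant_ec50_factor``.
    """

    name: str
    mic: float
    emax_kill: float = 6.0
    ec50: float | None = None
    hill: float = 1.0
    resistant_ec50_factor: float = 10.0

    def __post_init__(self) -> None:
        if self.mic <= 0:
            raise ValueError("mic must be positive")
        if self.emax_kill < 0:
            raise ValueError("emax_kill must be non-negative")
        if self.ec50 is not None and self.ec50 <= 0:
            raise ValueError("ec50 must be positive")
        if self.hill <= 0:
            raise ValueError("hill must be positive")

    @property
    def ec50_eff(self) -> float:
        return self.ec50 if self.ec50 is not None else self.mic


@dataclass(frozen=True)
class PDParameters:
    """System parameters of the growth/kill model (defaults are the
    published in-vitro values except ``b_max``, a conventional ceiling)."""

    k_growth: float = 1.70        # h^-1 natural growth
    k_death: float = 0.179        # h^-1 natural death
    b_max: float = 1e9            # CFU/ml stationary ceiling
    subpop_fraction: float = 0.819  # less-susceptible cells per 1e6 CFU/ml inoculum
    t_filament: float = 5.34      # h window of filament formation

    def __post_init__(self) -> None:
        if min(self.k_growth, self.k_death, self.b_max,
               self.subpop_fraction, self.t_filament) < 0:
            raise ValueError("PD parameters must be non-negative")
        if self.k_growth <= self.k_death:
            raise ValueError("k_growth must exceed k_death for a growing system")

    @property
    def capacity(self) -> float:
        """Internal logistic capacity giving a stationary total of b_max."""
        return self.b_max * self.k_growth / (self.k_growth - self.k_death)


@dataclass(frozen=True)
class ImmuneParameters:
    """Neutrophil kill term constants (in-vivo literature values)."""

    kkill_anc: float = 1.74       # h^-1 maximal neutrophil kill rate
    anc50: float = 190.8          # cells/ul for half-maximal kill
    b50: float = 430e4            # CFU/ml half-saturating burden
    anc: float = 2500.0           # cells/ul, constant neutrophil count

    def __post_init__(self) -> None:
        if min(self.kkill_anc, self.anc50, self.b50) <= 0 or self.anc < 0:
            raise ValueError("immune parameters must be positive (anc >= 0)")


def drug_kill_rate(c_unbound: float, strain: StrainParameters,
                   subpop: str = "susceptible") -> float:
    """Per-capita drug kill rate (h^-1) at unbound concentration ``c_unbound``."""
    if c_unbound < 0:
        raise ValueError("concentration must be non-negative")
    if subpop not in ("susceptible", "resistant"):
        raise ValueError("subpop must be 'susceptible' or 'resistant'")
    ec50 = strain.ec50_eff
    if subpop == "resistant":
        ec50 *= strain.resistant_ec50_factor
    ch = c_unbound ** strain.hill
    return strain.emax_kill * ch / (ec50 ** strain.hill + ch)


def immune_kill_rate(b_total: float, immune: ImmuneParameters) -> float:
    """Per-capita neutrophil kill rate (h^-1) at burden ``b_total``.

    First order in bacteria at low burden, saturating to zero-order (per
    capita rate -> 0) as the burden overwhelms the neutrophils.
    """
    if b_total < 0:
        raise ValueError("bacterial burden must be non-negative")
    anc_part = immune.anc / (immune.anc + immune.anc50)
    burden_part = 1.0 - b_total / (b_total + immune.b50)
    return immune.kkill_anc * anc_part * burden_part


@dataclass
class KillCurve:
    """Time course of the bacterial states for a strain panel.

    Arrays are time x strain; ``countable`` is ``b_s + b_r`` (filaments do
    not form colonies).
    """

    times: np.ndarray
    strains: list[str]
    b_s: np.ndarray
    b_r: np.ndarray
    b_f: np.ndarray

    @property
    def countable(self) -> np.ndarray:
        return self.b_s + self.b_r

    @property
    def total(self) -> np.ndarray:
        """All biomass including non-countable filaments."""
        return self.b_s + self.b_r + self.b_f

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, name in enumerate(self.strains):
            for comp, arr in (("susceptible", self.b_s), ("resistant", self.b_r),
                              ("filament", self.b_f)):
                rows.append(pd.DataFrame({
                    "time": self.times, "strain": name,
                    "compartment": comp, "cfu_per_ml": arr[:, k],
                }))
        return pd.concat(rows, ignore_index=True)


def floor_for_log(values: np.ndarray, floor: float = 1.0) -> np.ndarray:
    """Floor counts for log-scale plotting; the model state itself is
    continuous and never floored."""
    return np.maximum(values, floor)


def _as_conc_fn(profile) -> Callable[[float], float]:
    if callable(profile):
        return profile
    times, conc = profile
    times = np.asarray(times, dtype=float)
    conc = np.asarray(conc, dtype=float)
    return lambda t: float(np.interp(t, times, conc))


def _first_exposure(conc_fn: Callable[[float], float], horizon: float,
                    threshold: float = 1e-9) -> float | None:
    grid = np.linspace(0.0, horizon, 2001)
    vals = np.array([conc_fn(t) for t in grid])
    above = np.nonzero(vals > threshold)[0]
    return None if above.size == 0 else float(grid[above[0]])


def simulate_killing(
    profile,
    strains: Sequence[StrainParameters],
    pd_params: PDParameters | None = None,
    immune: ImmuneParameters | None = None,
    inoculum: float | Mapping[str, float] = 1e6,
    horizon: float = 24.0,
    t_eval: Sequence[float] | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-3,
    filament_clock: str = "exposure",
) -> KillCurve:
    """Integrate the growth/kill system under a drug concentration profile.

    Parameters
    ----------
    profile
        The unbound extracellular drug concentration at the infection site:
        a callable ``t -> mg/l`` or a ``(times, conc)`` pair covering
        ``[0, horizon]``.
    strains
        The strains co-inhabiting the site; they share the population
        ceiling and compete through it.
    inoculum
        Starting CFU/ml, one value for all strains or per-strain mapping.
        The less-susceptible subpopulation starts at
        ``subpop_fraction * inoculum / 1e6`` and the remainder is
        susceptible.
    filament_clock
        ``"exposure"`` starts the filamentation window at the first nonzero
        drug exposure (default); ``"start"`` starts it at time zero.

    Returns a :class:`KillCurve` sampled on ``t_eval`` (default: 0.05 h grid).
    """
    pd_params = pd_params or PDParameters()
    conc_fn = _as_conc_fn(profile)
    n = len(strains)
    if n == 0:
        raise ValueError("need at least one strain")
    if t_eval is None:
        t_eval = np.arange(0.0, horizon + 1e-9, 0.05)
    t_eval = np.asarray(t_eval, dtype=float)
    if t_eval[0] != 0.0 or t_eval[-1] > horizon:
        raise ValueError("t_eval must start at 0 and stay within the horizon")

    y0 = np.zeros(3 * n)
    for k, strain in enumerate(strains):
        inoc = inoculum[strain.name] if isinstance(inoculum, Mapping) else float(inoculum)
        if inoc <= 0:
            raise ValueError(f"inoculum for {strain.name!r} must be positive")
        b_r0 = pd_params.subpop_fraction * inoc / 1e6
        y0[3 * k] = inoc - b_r0
        y0[3 * k + 1] = b_r0

    if filament_clock == "exposure":
        t0 = _first_exposure(conc_fn, horizon)
    elif filament_clock == "start":
        t0 = 0.0
    else:
        raise ValueError("filament_clock must be 'exposure' or 'start'")
    t_switch = None if t0 is None else t0 + pd_params.t_filament

    cap = pd_params.capacity

    def rhs(t: float, y: np.ndarray, divert: bool) -> np.ndarray:
        b = np.maximum(y, 0.0)
        b_all = b.sum()
        growth = pd_params.k_growth * (1.0 - b_all / cap)
        ki = immune_kill_rate(b_all, immune) if immune is not None else 0.0
        c = conc_fn(t)
        dy = np.empty_like(y)
        for k, strain in enumerate(strains):
            bs, br, bf = b[3 * k], b[3 * k + 1], b[3 * k + 2]
            kd_s = drug_kill_rate(c, strain, "susceptible")
            kd_r = drug_kill_rate(c, strain, "resistant")
            flux_s = kd_s * bs
            flux_r = kd_r * br
            dy[3 * k] = (growth - pd_params.k_death - ki) * bs - flux_s
            dy[3 * k + 1] = (growth - pd_params.k_death - ki) * br - flux_r
            dy[3 * k + 2] = -(pd_params.k_death + ki) * bf
            if divert:
                dy[3 * k + 2] += flux_s + flux_r
        return dy

    # segment boundaries: first exposure and the end of the filament window
    cuts = [0.0, horizon]
    for c in (t0, t_switch):
        if c is not None and 0.0 < c < horizon:
            cuts.append(c)
    cuts = sorted(set(cuts))

    out = np.empty((t_eval.size, 3 * n))
    out[0] = y0
    y = y0.copy()
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        divert = t_switch is not None and t0 is not None and lo >= t0 and hi <= t_switch
        mask = (t_eval > lo) & (t_eval <= hi)
        te = t_eval[mask]
        sol = solve_ivp(rhs, (lo, hi), y, args=(divert,), method="LSODA",
                        t_eval=te if te.size else None, rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(f"bacterial PD integration failed: {sol.message}")
        if te.size:
            out[mask] = sol.y.T
        if te.size and te[-1] == hi:
            y = sol.y[:, -1].copy()
        else:
            sol_end = solve_ivp(rhs, (lo, hi), y, args=(divert,), method="LSODA",
                                t_eval=[hi], rtol=rtol, atol=atol)
            if not sol_end.success:
                raise RuntimeError(f"bacterial PD integration failed: {sol_end.message}")
            y = sol_end.y[:, -1].copy()

    scale = max(1.0, float(np.abs(out).max()))
    if np.any(out < -1e-6 * scale):
        raise RuntimeError("negative bacterial state from integrator; "
                           "tighten rtol/atol")
    out = np.maximum(out, 0.0)
    return KillCurve(
        times=t_eval, strains=[s.name for s in strains],
        b_s=out[:, 0::3], b_r=out[:, 1::3], b_f=out[:, 2::3],
    )


def default_strain_panel(config: Mapping | None = None) -> list[StrainParameters]:
    """The six-strain *E. coli* panel from the packaged config.

    MICs for LM347, LM625 and LM707 are the published values; the other
    MICs and all kill-rate parameters are documented defaults (see the
    config file), so simulations built on them are qualitative.
    """
    cfg = config or default_strains_config()
    d = cfg["defaults"]
    panel = []
    for name, spec in cfg["strains"].items():
        mic = float(spec["mic"])
        panel.append(StrainParameters(
            name=name, mic=mic,
            emax_kill=float(spec.get("emax_kill", d["emax_kill"])),
            ec50=float(spec["ec50"]) if "ec50" in spec else mic * float(d["ec50_per_mic"]),
            hill=float(spec.get("hill", d["hill"])),
            resistant_ec50_factor=float(spec.get("resistant_ec50_factor",
                                                 d["resistant_ec50_factor"])),
        ))
    return panel
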