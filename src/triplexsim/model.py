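"""Core tumor-immune competition model.

Ten coupled nonlinear ODEs describe the competition between the immune
system of a HER-2/neu transgenic mouse and mammary carcinoma cells under
Triplex whole-cell vaccination.  The populations (entity counts in a
simulated volume of 1 ul) are:

    VC    injected vaccine cells
    TAA   p185 tumor-associated antigen molecules
    B     activated plasma B cells
    TH    activated T helper cells
    IL12  interleukin-12 molecules
    IL2   interleukin-2 molecules
    AB    antibodies
    CC    cancer cells
    TC    activated cytotoxic T cells
    APC   activated antigen-presenting cells

One model time unit is one 8-hour step; every rate constant is per step.
Parameter naming follows the field convention for this model family:
``mu_i`` are natural death/degradation rates, ``alpha_ij`` interaction
rates between populations i and j, ``gamma_ij`` release/activation rates
of entity i by entity j, ``s_*`` interleukin saturation thresholds, plus
the tumor-growth constants (``k``, ``p``, ``c_max``) and the vaccine dose
``q``.

This module holds the state/parameter containers and the deterministic
right-hand side of the system.  Vaccine injections are impulses handled
by the simulator, not part of the vector field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace

import numpy as np

__all__ = [
    "STEPS_PER_DAY",
    "STEPS_PER_WEEK",
    "STATE_FIELDS",
    "STATE_LABELS",
    "PARAM_NAMES",
    "PARAM_DESCRIPTIONS",
    "ModelState",
    "ParameterSet",
    "default_parameters",
    "saturating_fraction",
    "rhs",
    "rhs_array",
]

# Time bookkeeping: the biology is observed on an 8-hour grid, so
# 3 steps = 1 day and 21 steps = 1 week.  All conversions go through
# these two constants.
STEPS_PER_DAY: int = 3
STEPS_PER_WEEK: int = 21

# Canonical ordering of the state vector; index i holds d<field>/dt in the
# rhs output as well.
STATE_FIELDS: tuple[str, ...] = (
    "vc", "taa", "b", "th", "il12", "il2", "ab", "cc", "tc", "apc",
)
# Upper-case labels used in CSV headers and reports.
STATE_LABELS: tuple[str, ...] = (
    "VC", "TAA", "B", "TH", "IL12", "IL2", "AB", "CC", "TC", "APC",
)


@dataclass(frozen=True)
class ModelState:
    """Counts of the ten modelled entities at one time point (per 1 ul)."""

    vc: float = 0.0
    taa: float = 0.0
    b: float = 0.0
    th: float = 0.0
    il12: float = 0.0
    il2: float = 0.0
    ab: float = 0.0
    cc: float = 0.0
    tc: float = 0.0
    apc: float = 0.0

    def __post_init__(self) -> None:
        for name in STATE_FIELDS:
            value = getattr(self, name)
            if not math.isfinite(value):
                raise ValueError(f"state field {name!r} is not finite: {value!r}")
            if value < 0:
                raise ValueError(f"state field {name!r} is negative: {value!r}")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in STATE_FIELDS], dtype=float)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "ModelState":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (len(STATE_FIELDS),):
            raise ValueError(f"expected shape (10,), got {arr.shape}")
        return cls(**dict(zip(STATE_FIELDS, arr.tolist())))


@dataclass
class ParameterSet:
    """The 44 model constants.

    Rates are per 8-hour step; ``s_*`` thresholds and ``c_max`` are counts;
    ``q`` is cells per injection.  Values may be scalars or equal-length
    numpy arrays (one value per batch member) — the right-hand side
    broadcasts either way.
    """

    # natural death / degradation rates
    mu_1: float = 0.0   # vaccine cells
    mu_2: float = 0.0   # tumor-associated antigen
    mu_3: float = 0.0   # plasma B cells
    mu_4: float = 0.0   # T helper cells
    mu_5: float = 0.0   # IL-12
    mu_6: float = 0.0   # IL-2
    mu_7: float = 0.0   # antibodies
    mu_9: float = 0.0   # cytotoxic T cells
    mu_0: float = 0.0   # antigen-presenting cells
    # interaction rates
    alpha_19: float = 0.0  # VC killing by TC
    alpha_17: float = 0.0  # VC killing by AB
    alpha_20: float = 0.0  # TAA capture by APC
    alpha_27: float = 0.0  # TAA-AB immune-complex formation
    alpha_36: float = 0.0  # B duplication stimulation by IL2
    alpha_46: float = 0.0  # TH duplication stimulation by IL2
    alpha_45: float = 0.0  # TH duplication stimulation by IL12
    alpha_54: float = 0.0  # IL12 absorption by TH
    alpha_59: float = 0.0  # IL12 absorption by TC
    alpha_63: float = 0.0  # IL2 absorption by B
    alpha_69: float = 0.0  # IL2 absorption by TC
    alpha_78: float = 0.0  # AB-CC binding
    alpha_71: float = 0.0  # AB-VC binding
    alpha_72: float = 0.0  # AB-TAA immune-complex formation
    alpha_88: float = 0.0  # CC killing by unmodelled effectors (e.g. NK)
    alpha_89: float = 0.0  # CC killing by TC
    alpha_87: float = 0.0  # CC killing by AB
    alpha_96: float = 0.0  # TC duplication stimulation by IL2
    # release / activation rates
    gamma_21: float = 0.0  # TAA released per killed VC
    gamma_28: float = 0.0  # TAA released per killed CC
    gamma_34: float = 0.0  # B activation by TH
    gamma_40: float = 0.0  # TH activation by APC
    gamma_51: float = 0.0  # IL12 released per killed VC
    gamma_64: float = 0.0  # IL2 release by TH
    gamma_73: float = 0.0  # AB release by B
    gamma_91: float = 0.0  # TC activation by VC
    gamma_02: float = 0.0  # APC activation by TAA
    # saturation thresholds (counts)
    s_1: float = 1.0    # IL2 threshold for TH stimulation
    s_2: float = 1.0    # IL12 threshold for TH stimulation
    s_3: float = 1.0    # IL2 threshold for B stimulation
    s_96: float = 1.0   # IL2 threshold for TC stimulation
    # tumor growth and dosing
    c_max: float = 1.0  # CC carrying capacity (cells)
    k: float = 0.0      # CC duplication rate per step
    p: float = 0.0      # newborn CC per step (transgenic influx)
    q: float = 0.0      # vaccine cells per injection

    def validate(self) -> None:
        for f in fields(self):
            value = np.asarray(getattr(self, f.name), dtype=float)
            if not np.all(np.isfinite(value)):
                raise ValueError(f"parameter {f.name!r} is not finite")
            if f.name in ("s_1", "s_2", "s_3", "s_96", "c_max"):
                if not np.all(value > 0):
                    raise ValueError(f"parameter {f.name!r} must be positive")
            elif not np.all(value >= 0):
                raise ValueError(f"parameter {f.name!r} must be nonnegative")

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, values: dict[str, float]) -> "ParameterSet":
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(values) - known)
        if unknown:
            raise ValueError(f"unknown parameter names: {', '.join(unknown)}")
        missing = sorted(known - set(values))
        if missing:
            raise ValueError(f"missing parameter names: {', '.join(missing)}")
        ps = cls(**{k: float(v) for k, v in values.items()})
        ps.validate()
        return ps

    def replace(self, **changes) -> "ParameterSet":
        return replace(self, **changes)


PARAM_NAMES: tuple[str, ...] = tuple(f.name for f in fields(ParameterSet))

PARAM_DESCRIPTIONS: dict[str, str] = {
    "mu_1": "VC natural death rate (half-life 9 steps)",
    "mu_2": "TAA natural degradation rate (half-life 9 steps)",
    "mu_3": "B-cell natural death rate (half-life 15 steps)",
    "mu_4": "TH natural death rate (half-life 15 steps)",
    "mu_5": "IL12 natural degradation rate (half-life 9 steps)",
    "mu_6": "IL2 natural degradation rate (half-life 3 steps)",
    "mu_7": "AB natural degradation rate (half-life 7 steps)",
    "mu_9": "TC natural death rate (half-life 21 steps)",
    "mu_0": "APC natural death rate (half-life 15 steps)",
    "alpha_19": "VC killing rate by TC",
    "alpha_17": "VC killing rate by AB",
    "alpha_20": "TAA-APC binding rate",
    "alpha_27": "TAA-AB binding rate (immune-complex formation)",
    "alpha_36": "B stimulation rate by IL2",
    "alpha_46": "TH stimulation rate by IL2 (duplication)",
    "alpha_45": "TH stimulation rate by IL12 (duplication)",
    "alpha_54": "IL12 absorbed by TH for mitotic signals",
    "alpha_59": "IL12 absorbed by TC for mitotic signals",
    "alpha_63": "IL2 absorbed by B for mitotic signals",
    "alpha_69": "IL2 absorbed by TC for mitotic signals",
    "alpha_78": "AB-CC binding rate",
    "alpha_71": "AB-VC binding rate",
    "alpha_72": "AB-TAA binding rate (immune-complex formation)",
    "alpha_88": "CC death rate due to other immune entities",
    "alpha_89": "CC killing rate by TC",
    "alpha_87": "CC killing rate by AB",
    "alpha_96": "TC duplication rate due to IL2",
    "gamma_21": "TAA release rate by killed VC",
    "gamma_28": "TAA release rate by killed CC",
    "gamma_34": "B activation rate by TH",
    "gamma_40": "TH activation rate by APC",
    "gamma_51": "IL12 release rate by killed VC",
    "gamma_64": "IL2 release rate by TH",
    "gamma_73": "AB release rate by B",
    "gamma_91": "TC activation rate by VC",
    "gamma_02": "APC activation rate by TAA",
    "s_1": "TH duplication stimulation threshold due to IL2",
    "s_2": "TH duplication stimulation threshold due to IL12",
    "s_3": "B duplication stimulation threshold due to IL2",
    "s_96": "TC duplication stimulation threshold due to IL2",
    "c_max": "CC growth saturation threshold (carrying capacity)",
    "k": "CC duplication rate per step",
    "p": "newborn CC per step (transgenic influx)",
    "q": "vaccine cells per injection",
}

_LN2 = math.log(2.0)


def default_parameters() -> ParameterSet:
    """Calibrated default parameter set.

    Death/degradation rates are ln(2)/t_half.  Half-lives of the fast
    entities are counted in 8-hour steps (vaccine cells 9 steps = 3 days,
    IL2 3 steps = 1 day, cytotoxic T cells 21 steps = 7 days, ...); the
    two humoral half-lives follow the values the immunology literature
    quotes in days — IgG antibodies about one week (21 steps) and plasma
    B cells about two weeks (45 steps).  This humoral persistence is what
    lets a short vaccination course protect for months before the tumor
    relapses.  The AB-TAA binding rate is the same in both directions of
    the immune complex, so alpha_72 = alpha_27.
    """
    ps = ParameterSet(
        mu_1=_LN2 / 9, mu_2=_LN2 / 9, mu_3=_LN2 / 45, mu_4=_LN2 / 15,
        mu_5=_LN2 / 9, mu_6=_LN2 / 3, mu_7=_LN2 / 21, mu_9=_LN2 / 21,
        mu_0=_LN2 / 15,
        alpha_19=0.001, alpha_17=0.001, alpha_20=0.0005, alpha_27=0.00001,
        alpha_36=0.0035, alpha_46=0.009, alpha_45=0.009, alpha_54=0.00009,
        alpha_59=0.001, alpha_63=0.0001, alpha_69=0.0001, alpha_78=0.0001,
        alpha_71=0.001, alpha_72=0.00001, alpha_88=0.0000001176,
        alpha_89=0.00004, alpha_87=0.00004, alpha_96=0.05,
        gamma_21=3.0, gamma_28=3.0, gamma_34=0.05, gamma_40=0.15,
        gamma_51=10.0, gamma_64=5.0, gamma_73=3.0, gamma_91=0.2,
        gamma_02=0.07,
        s_1=1000.0, s_2=1000.0, s_3=400.0, s_96=400.0,
        c_max=1e7, k=0.0226, p=3.0, q=50.0,
    )
    ps.validate()
    return ps


def saturating_fraction(x, s):
    """Michaelis-Menten style saturation x / (x + s).

    Used for the interleukin-driven stimulation of T-helper, B and
    cytotoxic T duplication; rises from 0 towards 1 as the interleukin
    count ``x`` passes the threshold ``s`` (half-maximal at x = s).
    Accepts scalars or arrays.
    """
    x_arr = np.asarray(x, dtype=float)
    s_arr = np.asarray(s, dtype=float)
    if not np.all(np.isfinite(x_arr)) or np.any(x_arr < 0):
        raise ValueError("saturating_fraction: x must be finite and nonnegative")
    if not np.all(np.isfinite(s_arr)) or np.any(s_arr <= 0):
        raise ValueError("saturating_fraction: s must be finite and positive")
    result = x_arr / (x_arr + s_arr)
    return float(result) if np.isscalar(x) and np.isscalar(s) else result


def rhs_array(y: np.ndarray, p: ParameterSet) -> np.ndarray:
    """Right-hand side on raw arrays.

    ``y`` has shape (..., 10) in STATE_FIELDS order; parameter values may
    be scalars or arrays broadcastable against ``y[..., 0]``.  Injections
    are impulses applied by the simulator and are not part of this vector
    field.  Returns d(state)/dt per 8-hour step, same shape as ``y``.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        bad = np.argwhere(~np.isfinite(y))
        name = STATE_FIELDS[int(bad[0][-1])]
        raise FloatingPointError(f"non-finite state component {name!r}")

    vc, taa, b, th, il12, il2, ab, cc, tc, apc = (y[..., i] for i in range(10))

    # loss rate of vaccine cells from killing + natural death; its release
    # products (TAA, IL12) are proportional to the same quantity
    vc_loss_rate = p.alpha_19 * tc + p.alpha_17 * ab + p.mu_1
    cc_kill_rate = p.alpha_89 * tc + p.alpha_87 * ab

    d = np.empty_like(y)
    d[..., 0] = -vc_loss_rate * vc
    # Antigen supply is carried by the vaccine cells: the secondary
    # release term scales with VC, not CC.  Tying it to cancer cells
    # would close a positive feedback loop (CC kill -> antigen -> APC ->
    # TH -> B -> AB -> more CC kill) that self-ignites without any
    # vaccination and makes the immune response permanent after a single
    # course, neither of which the modelled biology exhibits.
    d[..., 1] = (
        p.gamma_21 * vc_loss_rate * vc
        + p.gamma_28 * (p.alpha_88 + p.alpha_89 * tc) * vc
        - (p.mu_2 + p.alpha_20 * apc + p.alpha_27 * ab) * taa
    )
    d[..., 2] = (
        p.gamma_34 * th
        + p.alpha_36 * il2 / (il2 + p.s_3) * b
        - p.mu_3 * b
    )
    d[..., 3] = (
        p.gamma_40 * apc
        + p.alpha_46 * il2 / (il2 + p.s_1) * th
        + p.alpha_45 * il12 / (il12 + p.s_2) * th
        - p.mu_4 * th
    )
    d[..., 4] = (
        p.gamma_51 * vc_loss_rate * vc
        - (p.alpha_54 * th + p.alpha_59 * tc + p.mu_5) * il12
    )
    d[..., 5] = (
        p.gamma_64 * th
        - (p.alpha_63 * b + p.alpha_69 * tc) * il2
        - p.mu_6 * il2
    )
    d[..., 6] = (
        p.gamma_73 * b
        - (p.alpha_78 * cc + p.alpha_71 * vc + p.alpha_72 * taa) * ab
        - p.mu_7 * ab
    )
    # logistic growth minus background kill, both proportional to CC,
    # minus immune killing, plus the constant transgenic influx p
    d[..., 7] = (
        (p.k * (1.0 - cc / p.c_max) - p.alpha_88) * cc
        - cc_kill_rate * cc
        + p.p
    )
    d[..., 8] = (
        p.gamma_91 * vc
        + p.alpha_96 * il2 / (il2 + p.s_96) * tc
        - p.mu_9 * tc
    )
    d[..., 9] = p.gamma_02 * taa - p.mu_0 * apc
    return d


def rhs(state: ModelState, params: ParameterSet) -> np.ndarray:
    """Time derivative of the ten populations at ``state`` (per 8-h step)."""
    return rhs_array(state.to_array(), params)


def max_linear_loss_rate(y: np.ndarray, p: ParameterSet) -> float:
    """Largest instantaneous per-step linear loss rate across populations.

    At high antibody counts the mass-action loss terms (e.g. alpha_17*AB
    acting on VC) can reach tens per step, which makes the system locally
    stiff; the simulator uses this bound to keep the explicit integrator
    inside its stability region.
    """
    y = np.asarray(y, dtype=float)
    vc, taa, b, th, il12, il2, ab, cc, tc, apc = (y[..., i] for i in range(10))
    # a compartment that is exactly zero and has no active source
    # contributes no dynamics, however large its nominal loss rate (e.g.
    # alpha_78*CC on an antibody pool that never forms in an untreated
    # run), so such rows are masked out of the stiffness estimate
    candidates = [
        ((vc > 0), p.alpha_19 * tc + p.alpha_17 * ab + p.mu_1),
        ((taa > 0) | (vc > 0), p.mu_2 + p.alpha_20 * apc + p.alpha_27 * ab),
        ((il12 > 0) | (vc > 0), p.alpha_54 * th + p.alpha_59 * tc + p.mu_5),
        ((il2 > 0) | (th > 0), p.alpha_63 * b + p.alpha_69 * tc + p.mu_6),
        ((ab > 0) | (b > 0),
         p.alpha_78 * cc + p.alpha_71 * vc + p.alpha_72 * taa + p.mu_7),
        (True, p.alpha_89 * tc + p.alpha_87 * ab + p.k),
    ]
    return float(max(np.max(np.where(mask, lam, 0.0)) for mask, lam in candidates))
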