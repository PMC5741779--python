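"""Linear modelling of substituent effects against the catalytic field.

A substituent replacing a hydrogen perturbs the reaction mostly through
the charge it places near the old C–H axis, so the QM-computed barrier
change Δ (kcal mol⁻¹) of each substitution is regressed on the static
catalytic field Δs (kcal mol⁻¹ e⁻¹) at the site's probe.  Sites whose
hydrogen sits next to the reacting region are flagged and excluded from
the fit by default — there, non-electrostatic effects dominate and the
point-potential picture breaks down — but they are still predicted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import statsmodels.api as sm

from .catalytic_field import CatalyticFieldValue
from .errors import UsageError
from .structures_io import Molecule

__all__ = [
    "SubstitutionRecord",
    "LinearFieldModel",
    "fit_field_model",
    "predict_substituent_effects",
    "flag_near_reaction_sites",
    "rank_sites",
]


@dataclass(frozen=True)
class SubstitutionRecord:
    """One candidate H→substituent site and its field/barrier data."""

    site_label: str
    site_index: int  # 1-based H index
    delta_s: float  # kcal mol⁻¹ e⁻¹
    observed_delta: float | None = None  # kcal mol⁻¹, from QM barrier recomputation
    predicted_delta: float | None = None  # kcal mol⁻¹, from the linear model
    near_reaction: bool = False

    def __post_init__(self) -> None:
        for name in ("delta_s", "observed_delta", "predicted_delta"):
            v = getattr(self, name)
            if v is not None and not np.isfinite(v):
                raise UsageError(f"{name} must be finite, got {v!r}")


@dataclass(frozen=True)
class LinearFieldModel:
    """OLS fit of observed Δ on Δs.

    ``slope`` is dimensionally a charge (kcal mol⁻¹ per kcal mol⁻¹ e⁻¹ = e);
    ``residual_sd`` is sqrt(SSR / (n − p)).
    """

    slope: float
    intercept: float
    residual_sd: float
    n_used: int
    excluded_labels: tuple[str, ...]
    slope_se: float | None = None

    def predict(self, delta_s: float) -> float:
        return self.slope * delta_s + self.intercept

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "residual_sd": self.residual_sd,
            "n_used": self.n_used,
            "excluded_labels": list(self.excluded_labels),
            "slope_se": self.slope_se,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LinearFieldModel":
        return cls(
            slope=float(d["slope"]),
            intercept=float(d["intercept"]),
            residual_sd=float(d["residual_sd"]),
            n_used=int(d["n_used"]),
            excluded_labels=tuple(d.get("excluded_labels", ())),
            slope_se=d.get("slope_se"),
        )


def fit_field_model(
    records,
    use_intercept: bool = True,
    exclude=(),
    include_near_reaction: bool = False,
) -> LinearFieldModel:
    """Ordinary least squares of observed Δ on Δs.

    Records without an observed barrier change, records whose label is in
    *exclude*, and (by default) records flagged ``near_reaction`` are left
    out; all excluded labels are recorded verbatim on the model.
    """
    exclude = set(exclude)
    used, skipped = [], []
    for r in records:
        if r.observed_delta is None:
            continue
        if r.site_label in exclude or (r.near_reaction and not include_near_reaction):
            skipped.append(r.site_label)
        else:
            used.append(r)
    p = 2 if use_intercept else 1
    if len(used) < max(2, p):
        raise UsageError(
            f"need at least {max(2, p)} records with observed Δ after "
            f"exclusions, got {len(used)}"
        )
    x = np.array([r.delta_s for r in used])
    y = np.array([r.observed_delta for r in used])
    if np.ptp(x) < 1e-12:
        raise UsageError("degenerate design: Δs has zero variance across records")
    X = sm.add_constant(x) if use_intercept else x[:, None]
    res = sm.OLS(y, X).fit()
    slope = float(res.params[-1])
    intercept = float(res.params[0]) if use_intercept else 0.0
    df_resid = len(used) - p
    if df_resid > 0:
        residual_sd = float(np.sqrt(res.ssr / df_resid))
    else:
        warnings.warn(
            "saturated fit: zero residual degrees of freedom, residual SD "
            "reported as 0",
            stacklevel=2,
        )
        residual_sd = 0.0
    return LinearFieldModel(
        slope=slope,
        intercept=intercept,
        residual_sd=residual_sd,
        n_used=len(used),
        excluded_labels=tuple(skipped),
        slope_se=float(res.bse[-1]) if df_resid > 0 else None,
    )


def predict_substituent_effects(model: LinearFieldModel, records) -> list[SubstitutionRecord]:
    """Fill ``predicted_delta = slope·Δs + intercept`` for every record."""
    return [replace(r, predicted_delta=model.predict(r.delta_s)) for r in records]


def flag_near_reaction_sites(
    records, mol: Molecule, reacting_atoms, cutoff: float = 3.0
) -> list[SubstitutionRecord]:
    """Flag records whose site H lies within *cutoff* Å of a reacting atom.

    Flagged sites are excluded from fitting by default (see
    :func:`fit_field_model`) but still receive predictions.
    """
    pos = mol.positions
    for idx in reacting_atoms:
        if not 1 <= idx <= len(mol):
            raise UsageError(f"reacting atom index {idx} out of range 1..{len(mol)}")
    react = pos[[i - 1 for i in reacting_atoms]]
    out = []
    for r in records:
        if not 1 <= r.site_index <= len(mol):
            raise UsageError(
                f"record {r.site_label!r}: site index {r.site_index} out of range"
            )
        d = np.linalg.norm(react - pos[r.site_index - 1], axis=1)
        out.append(replace(r, near_reaction=bool(len(d) and d.min() < cutoff)))
    return out


def rank_sites(
    values: list[CatalyticFieldValue],
    objective: str = "lower",
    substituent_charge: float = -1.0,
) -> list[str]:
    """Order substitution sites by predicted barrier effect.

    A substituent carrying net charge q at the probe changes the barrier
    by Δ = −q·Δs (the single-charge consistency identity), so with the
    default q = −1 e (an electronegative substituent such as F) the most
    barrier-lowering sites are those with the most negative Δs.  Ties
    break by ascending site index.
    """
    if objective not in ("lower", "raise"):
        raise UsageError(f"objective must be 'lower' or 'raise', got {objective!r}")
    if any(v.probe.kind != "bond_directed" for v in values):
        raise UsageError("rank_sites requires bond-directed probe values only")
    sign = 1.0 if objective == "lower" else -1.0
    keyed = [
        (sign * (-substituent_charge * v.delta_s), v.probe.site_index) for v in values
    ]
    keyed.sort()
    return [str(idx) for _, idx in keyed]
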