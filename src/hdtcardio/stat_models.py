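"""Two-factorial mixed-model inference with focused Hochberg families.

Two model families mirror the study design:

* **time course** — normalized supine values at HDT2/HDT28/HDT56/R+10 modelled
  as Time x Group cell means with a subject random intercept; follow-up
  contrasts compare each timepoint against the baseline reference level
  (100 % for linear indices, 0 for log-scale indices) per group, or pooled
  over groups when only Time is significant, plus between-group differences
  at each timepoint;
* **postural test** — delta scores modelled as Posture x Group cell means
  with a subject random intercept; follow-up contrasts are the four non-zero
  tests (each group x posture delta vs 0), supine-vs-sitting within group and
  CTRL-vs-TRAIN within posture.

Follow-up contrasts are gatekept behind Type-III-style omnibus Wald tests of
the two factors and their interaction; contrasts requested while no omnibus
term is significant are still computed but flagged ``gated`` and excluded
from the correction family.  Families are deliberately small — one family per
outcome index per model — and corrected with the Hochberg step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DesignError, DomainError
from .mixedlm import MixedFit, WaldTest, fit_random_intercept
from .normalize import GROUPS, LOG_INDICES, POSTURES, TIMEPOINTS

FOLLOWUP_TIMEPOINTS = tuple(t for t in TIMEPOINTS if t != "BDC-7")


@dataclass
class ModelSpec:
    """Declaration of one outcome's mixed model and its contrast family."""

    outcome: str
    design: str  # "timecourse" | "postural"
    alpha: float = 0.05
    family: str | None = None

    def __post_init__(self) -> None:
        if self.design not in ("timecourse", "postural"):
            raise DomainError(f"unknown design {self.design!r}")
        if self.family is None:
            self.family = f"{self.design}:{self.outcome}"

    @property
    def baseline_null(self) -> float:
        """Reference level a normalized value reverts to at baseline."""
        if self.design == "postural":
            return 0.0
        return 0.0 if self.outcome in LOG_INDICES else 100.0


@dataclass
class ContrastResult:
    name: str
    estimate: float
    se: float
    df: float
    t: float
    p: float
    p_adj: float
    family: str
    gated: bool = False
    null_value: float = 0.0


@dataclass
class FittedIndexModel:
    spec: ModelSpec
    fit: MixedFit
    cells: list[tuple[str, str]]
    omnibus: dict[str, WaldTest] = field(default_factory=dict)

    def cell_vector(self, **which: str) -> np.ndarray:
        """Indicator vector selecting cells matching the given factor levels;
        multiple matches are averaged (unweighted adjusted means)."""
        sel = np.array(
            [
                all(v in cell for v in which.values())
                for cell in self.cells
            ],
            dtype=float,
        )
        if sel.sum() == 0:
            raise DesignError(f"no cell matches {which}")
        return sel / sel.sum()


def _factor_levels(design: str) -> tuple[str, tuple, str, tuple]:
    if design == "timecourse":
        return "group", GROUPS, "timepoint", FOLLOWUP_TIMEPOINTS
    return "group", GROUPS, "posture", POSTURES


def fit_mixed_model(df: pd.DataFrame, spec: ModelSpec) -> FittedIndexModel:
    """Fit one outcome's two-factorial random-intercept model (REML).

    The fixed part is parametrised by cell means (one coefficient per
    factor-level combination), which makes every follow-up contrast and the
    Type-III omnibus tests simple linear combinations of coefficients.
    """
    value_col = "delta" if "delta" in df.columns else "value"
    fac_a, lev_a, fac_b, lev_b = _factor_levels(spec.design)
    sub = df[df["index"] == spec.outcome] if "index" in df.columns else df
    if spec.design == "timecourse":
        sub = sub[(sub["posture"] == "supine") & (sub["timepoint"].isin(lev_b))]
    if sub.empty:
        raise DesignError(f"no rows for outcome {spec.outcome!r}")
    n_per_group = sub.groupby(fac_a)["subject"].nunique()
    if (n_per_group < 2).any() or len(n_per_group) < len(lev_a):
        raise DesignError("need >= 2 subjects in every group")
    cells = [(a, b) for a in lev_a for b in lev_b]
    X = np.zeros((len(sub), len(cells)))
    av = sub[fac_a].to_numpy()
    bv = sub[fac_b].to_numpy()
    for j, (a, b) in enumerate(cells):
        X[:, j] = (av == a) & (bv == b)
        if X[:, j].sum() == 0:
            raise DesignError(f"empty design cell ({a}, {b})")
    y = sub[value_col].to_numpy(dtype=float)
    fit = fit_random_intercept(
        y, X, sub["subject"].to_numpy(), fe_names=[f"{a}:{b}" for a, b in cells]
    )
    model = FittedIndexModel(spec=spec, fit=fit, cells=cells)
    model.omnibus = _omnibus_tests(model)
    return model


def _omnibus_tests(model: FittedIndexModel) -> dict[str, WaldTest]:
    """Type-III-style Wald tests of both factors and their interaction on the
    cell-mean parametrisation (unweighted marginal means)."""
    fac_a, lev_a, fac_b, lev_b = _factor_levels(model.spec.design)
    rows_a = [
        model.cell_vector(**{fac_a: lev_a[i]}) - model.cell_vector(**{fac_a: lev_a[0]})
        for i in range(1, len(lev_a))
    ]
    rows_b = [
        model.cell_vector(**{fac_b: lev_b[i]}) - model.cell_vector(**{fac_b: lev_b[0]})
        for i in range(1, len(lev_b))
    ]
    rows_ab = []
    for i in range(1, len(lev_a)):
        for j in range(1, len(lev_b)):
            v = np.zeros(len(model.cells))
            for sa, a in ((1, lev_a[i]), (-1, lev_a[0])):
                for sb, b in ((1, lev_b[j]), (-1, lev_b[0])):
                    v += sa * sb * np.array(
                        [1.0 if c == (a, b) else 0.0 for c in model.cells]
                    )
            rows_ab.append(v)
    names = {fac_a.capitalize(): rows_a, fac_b.capitalize(): rows_b,
             f"{fac_a.capitalize()}x{fac_b.capitalize()}": rows_ab}
    return {
        name: model.fit.wald(np.vstack(rows), name=name)
        for name, rows in names.items()
    }


def hochberg_adjust(p_values) -> np.ndarray:
    """Hochberg step-up adjusted p-values, returned in input order.

    Sort ascending; adj_i = min over j >= i of (m - j + 1) p_(j), capped at
    1.  Rejecting adj <= alpha reproduces the sequentially rejective step-up
    rule at every alpha, and the adjusted values are never smaller than the
    raw ones.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise DomainError("p-values must be a 1-d sequence")
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise DomainError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    mult = (m - np.arange(m)) * p[order]  # (m - j + 1) p_(j), j 1-based
    adj_sorted = np.minimum.accumulate(mult[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def _finalize_family(results: list[ContrastResult]) -> list[ContrastResult]:
    live = [r for r in results if not r.gated]
    if live:
        adj = hochberg_adjust([r.p for r in live])
        for r, a in zip(live, adj):
            r.p_adj = float(a)
    return results


def timecourse_contrasts(model: FittedIndexModel) -> list[ContrastResult]:
    """Follow-up contrasts of the time-course model with gatekeeping.

    With a significant Group effect or Time x Group interaction: per-group
    per-timepoint contrasts against the baseline reference plus between-group
    contrasts at each timepoint.  With only Time significant, the groups are
    pooled.  With no significant omnibus term every contrast is flagged
    ``gated`` and left out of the Hochberg family.
    """
    if model.spec.design != "timecourse":
        raise DomainError("timecourse_contrasts needs a timecourse model")
    alpha = model.spec.alpha
    om = model.omnibus
    sig_time = om["Timepoint"].p < alpha
    sig_group = om["Group"].p < alpha
    sig_int = om["GroupxTimepoint"].p < alpha
    null = model.spec.baseline_null
    per_group = sig_group or sig_int
    gated_all = not (sig_time or per_group)

    results: list[ContrastResult] = []

    def add(vec, name, null_value, gated):
        ct = model.fit.contrast(vec, null_value=null_value, name=name)
        results.append(
            ContrastResult(
                name=name, estimate=ct.estimate, se=ct.se, df=ct.df, t=ct.t,
                p=ct.p, p_adj=np.nan, family=model.spec.family, gated=gated,
                null_value=null_value,
            )
        )

    if per_group or gated_all:
        for g in GROUPS:
            for tp in FOLLOWUP_TIMEPOINTS:
                add(
                    model.cell_vector(group=g, timepoint=tp),
                    f"{g} {tp} vs baseline", null, gated_all,
                )
        for tp in FOLLOWUP_TIMEPOINTS:
            add(
                model.cell_vector(group="CTRL", timepoint=tp)
                - model.cell_vector(group="TRAIN", timepoint=tp),
                f"CTRL vs TRAIN at {tp}", 0.0, gated_all,
            )
    else:  # only Time significant: pool the groups
        for tp in FOLLOWUP_TIMEPOINTS:
            add(model.cell_vector(timepoint=tp), f"pooled {tp} vs baseline", null, False)
    return _finalize_family(results)


def delta_contrasts(model: FittedIndexModel) -> list[ContrastResult]:
    """Postural-test contrasts: the four non-zero tests (delta vs 0 per
    group x posture), supine vs sitting within group, and CTRL vs TRAIN
    within posture, gatekept behind the Posture/Group/interaction omnibus
    tests and Hochberg-corrected as one family."""
    if model.spec.design != "postural":
        raise DomainError("delta_contrasts needs a postural model")
    alpha = model.spec.alpha
    om = model.omnibus
    gated = not any(w.p < alpha for w in om.values())

    results: list[ContrastResult] = []

    def add(vec, name, null_value=0.0):
        ct = model.fit.contrast(vec, null_value=null_value, name=name)
        results.append(
            ContrastResult(
                name=name, estimate=ct.estimate, se=ct.se, df=ct.df, t=ct.t,
                p=ct.p, p_adj=np.nan, family=model.spec.family, gated=gated,
                null_value=null_value,
            )
        )

    for g in GROUPS:
        for pos in POSTURES:
            add(model.cell_vector(group=g, posture=pos), f"{g} {pos} delta vs 0")
    for g in GROUPS:
        add(
            model.cell_vector(group=g, posture="supine")
            - model.cell_vector(group=g, posture="sitting"),
            f"{g} supine vs sitting",
        )
    for pos in POSTURES:
        add(
            model.cell_vector(group="CTRL", posture=pos)
            - model.cell_vector(group="TRAIN", posture=pos),
            f"CTRL vs TRAIN {pos}",
        )
    return _finalize_family(results)


def contrasts_to_frame(results: list[ContrastResult]) -> pd.DataFrame:
    """Tabulate contrast results (one row per contrast)."""
    return pd.DataFrame(
        [
            {
                "contrast": r.name, "family": r.family, "estimate": r.estimate,
                "se": r.se, "df": r.df, "t": r.t, "p": r.p, "p_adj": r.p_adj,
                "gated": r.gated, "null_value": r.null_value,
            }
            for r in results
        ]
    )


def omnibus_to_frame(models: list[FittedIndexModel]) -> pd.DataFrame:
    """Factor-significance summary across outcomes (one row per outcome)."""
    rows = []
    for m in models:
        row = {"outcome": m.spec.outcome, "design": m.spec.design}
        for name, w in m.omnibus.items():
            row[f"p_{name}"] = w.p
        rows.append(row)
    return pd.DataFrame(rows)
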