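"""Tercile climatologies, probabilistic tercile forecasts, action levels, and
the monthly forecast report.

Monthly means are compared against climatological tercile bounds computed per
calendar month over a reference period (empirical 33.33% / 66.67% percentiles,
linear interpolation). A forecast's tercile probabilities are the fractions of
ensemble members falling below the lower bound (below-normal, pBN), above the
upper bound (above-normal, pAN) and in between (normal, pN); members exactly
equal to a bound count as normal. The above-normal DOC probability maps onto
four management action levels:

    watch (pAN < 0.60) · prepare (0.60 ≤ pAN < 0.70) ·
    act (0.70 ≤ pAN < 0.80) · escalate (pAN ≥ 0.80)

The monthly report carries, for four lead months, the DOC tercile forecast
with its action level and historical-skill class, plus the most probable
tercile of temperature, precipitation and streamflow for hydroclimatic
context. It is a static, machine-readable product (JSON) with a deterministic
Markdown rendering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .verification import SkillClass, SkillGrid, classify_skill

BELOW_NORMAL = "below-normal"
NORMAL = "normal"
ABOVE_NORMAL = "above-normal"
TERCILE_LABELS = (BELOW_NORMAL, NORMAL, ABOVE_NORMAL)

REPORT_LEADS = 4  # lead months shown in the monthly report


# ---------------------------------------------------------------------------
# Terciles
# ---------------------------------------------------------------------------


@dataclass
class TercileClimatology:
    """Per-calendar-month tercile bounds (t1 ≤ t2) over a reference period."""

    variable: str
    bounds: dict[int, tuple[float, float]]  # month → (t1, t2)
    ref_years: list[int]
    degenerate: dict[int, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if sorted(self.bounds) != list(range(1, 13)):
            raise ValueError("tercile climatology must cover all 12 calendar months")
        for m, (t1, t2) in self.bounds.items():
            if t1 > t2:
                raise ValueError(f"month {m}: lower tercile bound exceeds upper")


def tercile_bounds(values) -> tuple[float, float, bool]:
    """Empirical 33.33% and 66.67% percentiles of one calendar month's values.

    Returns (t1, t2, degenerate); degenerate flags an all-equal sample, whose
    bounds cannot split the distribution into informative categories.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 3:
        raise ValueError("tercile bounds need at least 3 values")
    t1, t2 = np.percentile(v, [100 / 3, 200 / 3])
    return float(t1), float(t2), bool(v.max() == v.min())


def tercile_climatology(
    monthly: dict[tuple[int, int], float], ref_years, variable: str = ""
) -> TercileClimatology:
    """Bounds for all 12 calendar months from a {(year, month): mean} record."""
    ref_years = list(ref_years)
    bounds, degenerate = {}, {}
    for m in range(1, 13):
        vals = [monthly[(y, m)] for y in ref_years if (y, m) in monthly]
        t1, t2, dg = tercile_bounds(vals)
        bounds[m] = (t1, t2)
        degenerate[m] = dg
    return TercileClimatology(variable, bounds, ref_years, degenerate)


@dataclass
class TercileForecast:
    """Tercile probabilities of one lead month's ensemble."""

    p_below: float
    p_normal: float
    p_above: float
    n_members: int
    most_probable: str

    def probabilities(self) -> tuple[float, float, float]:
        return self.p_below, self.p_normal, self.p_above


def tercile_probabilities(ensemble, bounds: tuple[float, float]) -> TercileForecast:
    """Fraction of members below t1 / between / above t2 (bound-equal → normal)."""
    x = np.asarray(ensemble, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("empty ensemble")
    t1, t2 = bounds
    p_b = float(np.mean(x < t1))
    p_a = float(np.mean(x > t2))
    p_n = 1.0 - p_b - p_a
    return TercileForecast(p_b, p_n, p_a, int(x.size),
                           most_probable_tercile((p_b, p_n, p_a)))


def most_probable_tercile(probabilities) -> str:
    """Argmax tercile; ties resolve toward normal, then toward the lower tercile."""
    p_b, p_n, p_a = probabilities
    if not np.isclose(p_b + p_n + p_a, 1.0, atol=1e-9):
        raise ValueError("tercile probabilities must sum to 1")
    best = max(p_b, p_n, p_a)
    if p_n == best:  # tie rule: normal wins any tie it is part of
        return NORMAL
    if p_b == best:  # then the lower tercile
        return BELOW_NORMAL
    return ABOVE_NORMAL


# ---------------------------------------------------------------------------
# Action levels
# ---------------------------------------------------------------------------


class ActionLevel(str, Enum):
    WATCH = "watch"
    PREPARE = "prepare"
    ACT = "act"
    ESCALATE = "escalate"


def action_level(p_above: float) -> ActionLevel:
    """Management action level from the above-normal DOC probability."""
    if not 0.0 <= p_above <= 1.0:
        raise ValueError(f"pAN out of range: {p_above}")
    if p_above >= 0.80:
        return ActionLevel.ESCALATE
    if p_above >= 0.70:
        return ActionLevel.ACT
    if p_above >= 0.60:
        return ActionLevel.PREPARE
    return ActionLevel.WATCH


# ---------------------------------------------------------------------------
# Monthly report
# ---------------------------------------------------------------------------


@dataclass
class ReportLead:
    lead: int
    calendar_month: int
    doc: TercileForecast
    doc_action: ActionLevel
    doc_skill: SkillClass | None  # None = "no skill information" for that cell
    context: dict[str, str]  # variable → most probable tercile label


@dataclass
class MonthlyReport:
    init_year: int
    init_month: int
    leads: list[ReportLead]
    provenance: dict

    def __post_init__(self) -> None:
        if len(self.leads) != REPORT_LEADS:
            raise ValueError(f"report must carry exactly {REPORT_LEADS} lead months")

    def to_dict(self) -> dict:
        return {
            "init": f"{self.init_year:04d}-{self.init_month:02d}",
            "leads": [
                {
                    "lead": ld.lead,
                    "calendar_month": ld.calendar_month,
                    "doc": {
                        "p_below": ld.doc.p_below,
                        "p_normal": ld.doc.p_normal,
                        "p_above": ld.doc.p_above,
                        "n_members": ld.doc.n_members,
                        "most_probable": ld.doc.most_probable,
                    },
                    "action_level": ld.doc_action.value,
                    "skill_class": ld.doc_skill.value if ld.doc_skill else None,
                    "context": ld.context,
                }
                for ld in self.leads
            ],
            "provenance": self.provenance,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


_MONTH_NAMES = ("January", "February", "March", "April", "May", "June", "July",
                "August", "September", "October", "November", "December")


def assemble_report(
    init_year: int,
    init_month: int,
    ensembles: dict[str, dict[int, np.ndarray]],  # variable → lead → member monthly means
    climatologies: dict[str, TercileClimatology],
    skill_grid: SkillGrid,
    provenance: dict | None = None,
) -> MonthlyReport:
    """Assemble the machine-readable monthly report for four lead months.

    `ensembles` must cover the variables "doc", "temperature", "precipitation"
    and "streamflow" for at least the first four leads. A skill cell flagged
    missing in the verification grid is carried as absent skill information,
    never as a fabricated class.
    """
    leads = []
    for lead in range(1, REPORT_LEADS + 1):
        month = (init_month - 1 + lead - 1) % 12 + 1
        doc_fc = tercile_probabilities(
            ensembles["doc"][lead], climatologies["doc"].bounds[month]
        )
        cell = skill_grid.cell(init_month, lead)
        context = {}
        for var in ("temperature", "precipitation", "streamflow"):
            fc = tercile_probabilities(
                ensembles[var][lead], climatologies[var].bounds[month]
            )
            context[var] = fc.most_probable
        leads.append(
            ReportLead(
                lead=lead,
                calendar_month=month,
                doc=doc_fc,
                doc_action=action_level(doc_fc.p_above),
                doc_skill=classify_skill(cell) if np.isfinite(cell) else None,
                context=context,
            )
        )
    prov = {
        "n_members": leads[0].doc.n_members,
        "tercile_reference": {
            var: [int(min(c.ref_years)), int(max(c.ref_years))]
            for var, c in climatologies.items()
        },
    }
    if provenance:
        prov.update(provenance)
    return MonthlyReport(init_year, init_month, leads, prov)


def render_markdown(report: MonthlyReport) -> str:
    """Deterministic plain-text rendering of the monthly report."""
    lines = [
        f"# Seasonal DOC forecast — initialized {report.init_year:04d}-{report.init_month:02d}",
        "",
        "| Lead | Month | pBN | pN | pAN | Most probable | Action | Skill |",
        "|------|-------|-----|----|-----|---------------|--------|-------|",
    ]
    for ld in report.leads:
        skill = ld.doc_skill.value if ld.doc_skill else "no skill information"
        lines.append(
            f"| {ld.lead} | {_MONTH_NAMES[ld.calendar_month - 1]} "
            f"| {ld.doc.p_below:.0%} | {ld.doc.p_normal:.0%} | {ld.doc.p_above:.0%} "
            f"| {ld.doc.most_probable} | {ld.doc_action.value} | {skill} |"
        )
    lines.append("")
    lines.append("Hydroclimatic context (most probable tercile):")
    lines.append("")
    for ld in report.leads:
        ctx = ", ".join(f"{k}: {v}" for k, v in sorted(ld.context.items()))
        lines.append(f"- Lead {ld.lead} ({_MONTH_NAMES[ld.calendar_month - 1]}): {ctx}")
    ref = report.provenance.get("tercile_reference", {})
    if ref:
        lines.append("")
        refs = "; ".join(f"{v}: {a}–{b}" for v, (a, b) in sorted(ref.items()))
        lines.append(f"Tercile reference periods — {refs}. "
                     f"Ensemble size {report.provenance.get('n_members', '?')}.")
    return "\n".join(lines) + "\n"
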