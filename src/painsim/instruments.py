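"""Declarative questionnaire scoring and the pre/post statistical battery.

Four instruments are bundled (see ``painsim/data/instruments/``):

* ``attrakdiff2`` — 28 semantic-differential items on a 7-step scale,
  four 7-item subscales (PQ, HQ-I, HQ-S, ATT), each scored as the mean of
  its items mapped to -3..+3 with reverse-keyed items flipped.
* ``pop_mgs`` — 12 ease-of-use/usefulness Likert items, 0-5.
* ``bq2`` — 27 barriers items, 0-5, four subscales; higher = more barriers.
* ``pak_ppm`` — 15 multiple-choice knowledge items, 6 options each with a
  single correct answer ("do not know" counts incorrect), scored as the
  percentage of correct answers.

The statistics mirror the analysis plan of a small pre/post usability
study: median and Tukey-hinge IQR, the Wilcoxon signed-rank test (exact
by full sign enumeration for small n, tie-corrected normal approximation
otherwise), Cronbach alpha and its dichotomous special case KR-20.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from typing import Any, Iterable, Optional

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ContractViolation, UsageError

INSTRUMENT_KINDS = frozenset({"semantic_differential", "likert", "multiple_choice"})
AGGREGATIONS = frozenset({"mean", "median", "proportion_correct"})

#: exact Wilcoxon enumeration is used up to this many non-zero differences
EXACT_WILCOXON_MAX_N = 15


# ---------------------------------------------------------------------
# instrument definitions
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class ItemSpec:
    id: str
    subscale: str
    reverse: bool = False
    correct: Optional[int] = None  # multiple_choice only
    left: str = ""
    right: str = ""


@dataclass(frozen=True)
class InstrumentSpec:
    name: str
    kind: str
    scale_min: int
    scale_max: int
    items: tuple[ItemSpec, ...]
    subscales: dict[str, str]  # subscale id -> aggregation
    n_options: Optional[int] = None  # multiple_choice only

    def __post_init__(self) -> None:
        if self.kind not in INSTRUMENT_KINDS:
            raise ConfigurationError(f"{self.name}: unknown kind {self.kind!r}")
        if self.scale_min >= self.scale_max:
            raise ConfigurationError(f"{self.name}: empty response scale")
        for agg in self.subscales.values():
            if agg not in AGGREGATIONS:
                raise ConfigurationError(f"{self.name}: unknown aggregation {agg!r}")
        seen = set()
        for item in self.items:
            if item.id in seen:
                raise ConfigurationError(f"{self.name}: duplicate item {item.id}")
            seen.add(item.id)
            if item.subscale not in self.subscales:
                raise ConfigurationError(
                    f"{self.name}: item {item.id} references unknown subscale"
                )
            if self.kind == "multiple_choice":
                if item.correct is None:
                    raise ConfigurationError(
                        f"{self.name}: item {item.id} has no correct answer"
                    )
                if not (1 <= item.correct <= (self.n_options or 0)):
                    raise ConfigurationError(
                        f"{self.name}: item {item.id} correct answer out of range"
                    )

    @property
    def item_ids(self) -> list[str]:
        return [i.id for i in self.items]

    def item(self, item_id: str) -> ItemSpec:
        for i in self.items:
            if i.id == item_id:
                return i
        raise ConfigurationError(f"{self.name}: unknown item {item_id!r}")


def instrument_from_dict(d: dict[str, Any]) -> InstrumentSpec:
    try:
        items = tuple(
            ItemSpec(
                id=i["id"],
                subscale=i["subscale"],
                reverse=bool(i.get("reverse", False)),
                correct=i.get("correct"),
                left=i.get("left", ""),
                right=i.get("right", ""),
            )
            for i in d["items"]
        )
        return InstrumentSpec(
            name=d["name"],
            kind=d["kind"],
            scale_min=int(d["scale_min"]),
            scale_max=int(d["scale_max"]),
            items=items,
            subscales=dict(d["subscales"]),
            n_options=d.get("n_options"),
        )
    except KeyError as exc:
        raise ConfigurationError(f"instrument definition missing field {exc}") from None


def load_instrument_file(path: str) -> InstrumentSpec:
    with open(path) as fh:
        return instrument_from_dict(json.load(fh))


# ---------------------------------------------------------------------
# response sheets
# ---------------------------------------------------------------------


@dataclass
class ResponseSheet:
    """One respondent's answers to one instrument at one timepoint."""

    respondent: str
    instrument: str
    answers: dict[str, Optional[int]]
    timepoint: Optional[str] = None  # "pre" | "post" | None

    def missing_items(self, spec: InstrumentSpec) -> list[str]:
        return [
            i for i in spec.item_ids
            if i not in self.answers or self.answers[i] is None
        ]


def validate_sheet(sheet: ResponseSheet, spec: InstrumentSpec) -> None:
    hi = spec.n_options if spec.kind == "multiple_choice" else spec.scale_max
    lo = 1 if spec.kind == "multiple_choice" else spec.scale_min
    for item_id, ans in sheet.answers.items():
        spec.item(item_id)  # raises on unknown item
        if ans is not None and not (lo <= ans <= hi):
            raise ContractViolation(
                f"{sheet.respondent}/{spec.name}: answer {ans} to {item_id} "
                f"outside [{lo}, {hi}]"
            )


def load_response_sheets(path: str) -> list[ResponseSheet]:
    """Read long-format CSV: respondent, instrument, timepoint, item, answer."""
    df = pd.read_csv(path, dtype={"respondent": str, "item": str})
    required = {"respondent", "instrument", "timepoint", "item", "answer"}
    if not required <= set(df.columns):
        raise ConfigurationError(
            f"responses file must have columns {sorted(required)}"
        )
    sheets = []
    for (resp, inst, tp), grp in df.groupby(
        ["respondent", "instrument", "timepoint"], dropna=False, sort=True
    ):
        answers = {
            str(r.item): (None if pd.isna(r.answer) else int(r.answer))
            for r in grp.itertuples()
        }
        sheets.append(
            ResponseSheet(
                respondent=str(resp),
                instrument=str(inst),
                answers=answers,
                timepoint=None if pd.isna(tp) else str(tp),
            )
        )
    return sheets


def sheets_to_frame(sheets: Iterable[ResponseSheet]) -> pd.DataFrame:
    rows = []
    for s in sheets:
        for item, ans in s.answers.items():
            rows.append(
                {
                    "respondent": s.respondent,
                    "instrument": s.instrument,
                    "timepoint": s.timepoint if s.timepoint is not None else "",
                    "item": item,
                    "answer": ans,
                }
            )
    return pd.DataFrame(rows, columns=["respondent", "instrument", "timepoint", "item", "answer"])


# ---------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------


@dataclass
class ScoreResult:
    respondent: str
    instrument: str
    timepoint: Optional[str]
    subscales: dict[str, float]
    total: Optional[float]
    items: dict[str, float] = field(default_factory=dict)
    missing: list[str] = field(default_factory=list)


def map_semantic_differential(spec: InstrumentSpec, item: ItemSpec, raw: int) -> float:
    """Map a raw 1..7 step to -3..+3; reverse-keyed items are mirrored."""
    mid = (spec.scale_min + spec.scale_max) / 2.0
    value = raw - mid
    return -value if item.reverse else value


def reverse_key(spec: InstrumentSpec, item: ItemSpec, raw: int) -> int:
    """Mirror a raw response on its scale (an involution)."""
    return spec.scale_min + spec.scale_max - raw


def score_attrakdiff(sheet: ResponseSheet, spec: InstrumentSpec) -> ScoreResult:
    """Subscale means of pole-mapped items; each score lies in [-3, 3].

    Missing items are excluded from their subscale mean with a warning.
    """
    if spec.kind != "semantic_differential":
        raise UsageError("score_attrakdiff requires a semantic_differential spec")
    validate_sheet(sheet, spec)
    missing = sheet.missing_items(spec)
    if missing:
        warnings.warn(
            f"{sheet.respondent}/{spec.name}: missing items excluded: {missing}",
            stacklevel=2,
        )
    mapped: dict[str, float] = {}
    for item in spec.items:
        raw = sheet.answers.get(item.id)
        if raw is not None:
            mapped[item.id] = map_semantic_differential(spec, item, raw)
    subscales = {}
    for sub in spec.subscales:
        vals = [mapped[i.id] for i in spec.items if i.subscale == sub and i.id in mapped]
        subscales[sub] = float(np.mean(vals)) if vals else float("nan")
    return ScoreResult(
        respondent=sheet.respondent,
        instrument=spec.name,
        timepoint=sheet.timepoint,
        subscales=subscales,
        total=float(np.mean(list(mapped.values()))) if mapped else float("nan"),
        items=mapped,
        missing=missing,
    )


def score_proportion_correct(sheet: ResponseSheet, spec: InstrumentSpec) -> ScoreResult:
    """Percent correct over all items; unanswered and "do not know" count
    incorrect (unanswered items are additionally flagged)."""
    if spec.kind != "multiple_choice":
        raise UsageError("score_proportion_correct requires a multiple_choice spec")
    validate_sheet(sheet, spec)
    missing = sheet.missing_items(spec)
    item_scores = {}
    for item in spec.items:
        ans = sheet.answers.get(item.id)
        item_scores[item.id] = 1.0 if ans == item.correct else 0.0
    percent = 100.0 * sum(item_scores.values()) / len(spec.items)
    return ScoreResult(
        respondent=sheet.respondent,
        instrument=spec.name,
        timepoint=sheet.timepoint,
        subscales={
            sub: 100.0 * float(
                np.mean([item_scores[i.id] for i in spec.items if i.subscale == sub])
            )
            for sub in spec.subscales
        },
        total=percent,
        items=item_scores,
        missing=missing,
    )


def score_likert(sheet: ResponseSheet, spec: InstrumentSpec) -> ScoreResult:
    """Per-item values plus subscale and total aggregates (reverse keying
    applied). Out-of-scale answers raise a validation error naming the item."""
    if spec.kind != "likert":
        raise UsageError("score_likert requires a likert spec")
    validate_sheet(sheet, spec)
    missing = sheet.missing_items(spec)
    if missing:
        warnings.warn(
            f"{sheet.respondent}/{spec.name}: missing items excluded: {missing}",
            stacklevel=2,
        )
    values: dict[str, float] = {}
    for item in spec.items:
        raw = sheet.answers.get(item.id)
        if raw is None:
            continue
        values[item.id] = float(reverse_key(spec, item, raw) if item.reverse else raw)
    subscales = {}
    for sub, agg in spec.subscales.items():
        vals = [values[i.id] for i in spec.items if i.subscale == sub and i.id in values]
        if not vals:
            subscales[sub] = float("nan")
        elif agg == "median":
            subscales[sub] = float(np.median(vals))
        else:
            subscales[sub] = float(np.mean(vals))
    return ScoreResult(
        respondent=sheet.respondent,
        instrument=spec.name,
        timepoint=sheet.timepoint,
        subscales=subscales,
        total=float(np.mean(list(values.values()))) if values else float("nan"),
        items=values,
        missing=missing,
    )


def score_sheet(sheet: ResponseSheet, spec: InstrumentSpec) -> ScoreResult:
    """Route a sheet to the scorer matching its instrument kind."""
    if spec.kind == "semantic_differential":
        return score_attrakdiff(sheet, spec)
    if spec.kind == "multiple_choice":
        return score_proportion_correct(sheet, spec)
    return score_likert(sheet, spec)


# ---------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------


def median_iqr(values: Iterable[float], method: str = "tukey") -> tuple[float, float]:
    """Median and interquartile range (Q3 - Q1).

    ``method='tukey'`` uses Tukey hinges (each half includes the median
    for odd n); ``method='linear'`` uses numpy's default interpolated
    quartiles.
    """
    x = np.sort(np.asarray(list(values), dtype=float))
    if x.size == 0:
        raise ContractViolation("median_iqr requires at least one value")
    med = float(np.median(x))
    if method == "tukey":
        h = (x.size + 1) // 2
        q1 = float(np.median(x[:h]))
        q3 = float(np.median(x[x.size - h:]))
    elif method == "linear":
        q1, q3 = (float(q) for q in np.percentile(x, [25, 75]))
    else:
        raise UsageError(f"unknown quantile method {method!r}")
    return med, q3 - q1


@dataclass(frozen=True)
class WilcoxonResult:
    w_plus: float
    w_minus: float
    n: int  # differences entering the ranking
    z: float
    p: float
    method: str  # "exact" | "normal" | "degenerate"
    alternative: str
    n_zero: int  # zero differences observed


def wilcoxon_signed_rank(
    pre: Iterable[float],
    post: Iterable[float],
    zero_policy: str = "discard",
    mode: str = "auto",
    alternative: str = "two-sided",
) -> WilcoxonResult:
    """Wilcoxon signed-rank test on paired samples (differences post - pre).

    Exact p-values come from full enumeration of all 2^n sign assignments
    of the (tie-averaged) ranks, used when ``mode='exact'`` or in auto
    mode with at most ``EXACT_WILCOXON_MAX_N`` non-zero differences;
    otherwise a normal approximation with tie-corrected variance is used
    (no continuity correction). Zero differences are discarded by default
    (``zero_policy='pratt'`` keeps them in the ranking but not in W).
    Z is signed like ``w_plus`` relative to its null mean, so an overall
    increase gives positive Z.
    """
    pre = np.asarray(list(pre), dtype=float)
    post = np.asarray(list(post), dtype=float)
    if pre.shape != post.shape or pre.size == 0:
        raise ContractViolation("paired vectors of equal length >= 1 required")
    if zero_policy not in ("discard", "pratt"):
        raise UsageError(f"unknown zero_policy {zero_policy!r}")
    if alternative not in ("two-sided", "greater", "less"):
        raise UsageError(f"unknown alternative {alternative!r}")
    d = post - pre
    n_zero = int(np.sum(d == 0))
    if zero_policy == "discard":
        d = d[d != 0]
    if d.size == 0 or np.all(d == 0):
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return WilcoxonResult(
            w_plus=float("nan"), w_minus=float("nan"), n=0, z=0.0, p=1.0,
            method="degenerate", alternative=alternative, n_zero=n_zero,
        )

    ranks = pd.Series(np.abs(d)).rank(method="average").to_numpy()
    signed = ranks * np.sign(d)  # pratt: zero diffs get rank but sign 0
    w_plus = float(signed[signed > 0].sum())
    w_minus = float(-signed[signed < 0].sum())
    active = ranks[np.sign(d) != 0]
    mu = float(active.sum()) / 2.0
    sigma2 = float(np.sum(active**2)) / 4.0
    n_eff = int(np.sum(np.sign(d) != 0))

    use_exact = mode == "exact" or (mode == "auto" and n_eff <= EXACT_WILCOXON_MAX_N)
    if mode not in ("auto", "exact", "normal"):
        raise UsageError(f"unknown mode {mode!r}")

    z = (w_plus - mu) / np.sqrt(sigma2) if sigma2 > 0 else 0.0

    if use_exact:
        dist = _exact_wplus_distribution(active)
        if alternative == "greater":
            p = float(dist[dist >= w_plus - 1e-9].size) / dist.size
        elif alternative == "less":
            p = float(dist[dist <= w_plus + 1e-9].size) / dist.size
        else:
            dev = abs(w_plus - mu)
            p = float(np.sum(np.abs(dist - mu) >= dev - 1e-9)) / dist.size
        method = "exact"
    else:
        from scipy.stats import norm

        if alternative == "greater":
            p = float(norm.sf(z))
        elif alternative == "less":
            p = float(norm.cdf(z))
        else:
            p = float(2.0 * norm.sf(abs(z)))
        method = "normal"
    return WilcoxonResult(
        w_plus=w_plus, w_minus=w_minus, n=n_eff, z=float(z), p=min(1.0, p),
        method=method, alternative=alternative, n_zero=n_zero,
    )


def _exact_wplus_distribution(ranks: np.ndarray) -> np.ndarray:
    """W+ under every one of the 2^n equally likely sign assignments."""
    n = ranks.size
    if n > 20:  # 2^20 already ~1e6; guard against misuse
        raise UsageError("exact enumeration limited to n <= 20")
    signs = np.array(list(itertools.product((0.0, 1.0), repeat=n)))
    return signs @ ranks


def cronbach_alpha(item_matrix: np.ndarray | pd.DataFrame) -> float:
    """Cronbach alpha: k/(k-1) * (1 - sum of item variances / total variance).

    Sample (ddof=1) variances. Missing values are handled by pairwise
    exclusion through the covariance matrix: the total variance is the
    sum of all pairwise covariances.
    """
    df = pd.DataFrame(item_matrix)
    k = df.shape[1]
    if k < 2 or df.shape[0] < 2:
        raise ContractViolation("alpha needs >= 2 items and >= 2 respondents")
    cov = df.cov()  # pairwise-complete by construction
    total_var = float(cov.to_numpy().sum())
    if total_var <= 0 or not np.isfinite(total_var):
        raise ContractViolation("total score variance is zero or undefined")
    item_var = float(np.trace(cov.to_numpy()))
    return k / (k - 1) * (1.0 - item_var / total_var)


def kr20(binary_matrix: np.ndarray | pd.DataFrame) -> float:
    """Kuder-Richardson formula 20 for dichotomous (0/1) items.

    Uses sample-variance scaling n/(n-1) on the p(1-p) item terms so that
    KR-20 coincides exactly with Cronbach alpha on the same 0/1 matrix.
    """
    x = pd.DataFrame(binary_matrix).to_numpy(dtype=float)
    if not np.isin(x[~np.isnan(x)], (0.0, 1.0)).all():
        raise ContractViolation("kr20 requires 0/1 scoring")
    n, k = x.shape
    if k < 2 or n < 2:
        raise ContractViolation("kr20 needs >= 2 items and >= 2 respondents")
    p = np.nanmean(x, axis=0)
    item_var = p * (1 - p) * n / (n - 1)
    totals = np.nansum(x, axis=1)
    total_var = float(np.var(totals, ddof=1))
    if total_var <= 0:
        raise ContractViolation("total score variance is zero")
    return k / (k - 1) * (1.0 - float(item_var.sum()) / total_var)


# ---------------------------------------------------------------------
# pre/post comparison driver
# ---------------------------------------------------------------------


def compare_pre_post(
    sheets: list[ResponseSheet],
    spec: InstrumentSpec,
    alternative: str = "two-sided",
) -> dict[str, Any]:
    """Score paired pre/post sheets and run the signed-rank comparison.

    Respondents lacking either timepoint are excluded listwise (and
    reported). Summaries use median and Tukey-hinge IQR.
    """
    by_resp: dict[str, dict[str, ResponseSheet]] = {}
    for s in sheets:
        if s.instrument != spec.name or s.timepoint not in ("pre", "post"):
            continue
        by_resp.setdefault(s.respondent, {})[s.timepoint] = s
    paired = sorted(r for r, d in by_resp.items() if {"pre", "post"} <= set(d))
    excluded = sorted(set(by_resp) - set(paired))
    if not paired:
        raise ContractViolation("no respondents with both pre and post sheets")
    pre_scores = [score_sheet(by_resp[r]["pre"], spec).total for r in paired]
    post_scores = [score_sheet(by_resp[r]["post"], spec).total for r in paired]
    res = wilcoxon_signed_rank(pre_scores, post_scores, alternative=alternative)
    med_pre, iqr_pre = median_iqr(pre_scores)
    med_post, iqr_post = median_iqr(post_scores)
    return {
        "instrument": spec.name,
        "n_pairs": len(paired),
        "excluded_respondents": excluded,
        "pre": {"median": med_pre, "iqr": iqr_pre},
        "post": {"median": med_post, "iqr": iqr_post},
        "wilcoxon": {
            "w_plus": res.w_plus,
            "w_minus": res.w_minus,
            "n": res.n,
            "z": res.z,
            "p": res.p,
            "method": res.method,
            "alternative": res.alternative,
            "n_zero": res.n_zero,
        },
    }
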