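"""Within-subject ANOVA screening, Bonferroni correction, post-hoc paired
t-tests, and control-experiment agreement rates.

The screen runs one 2x2 repeated-measures ANOVA per musical dimension, with
the pianist as the random blocking factor and valence x category as
within-subject factors.  Each pianist x cell is first collapsed to the mean
over its 8 words, giving numerator df = 1 for every effect and denominator
df = n_pianists - 1.  Sums of squares are computed explicitly (balanced
design), with each effect tested against its own effect-by-subject
interaction term.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .corpus_io import CATEGORIES, VALENCES
from .features import FEATURE_NAMES

log = logging.getLogger(__name__)

EFFECTS = ("valence", "category", "interaction")


class IncompleteDesignError(ValueError):
    """A pianist is missing data in one of the four design cells."""


@dataclass(frozen=True)
class EffectResult:
    F: float
    p: float
    df_num: int
    df_den: int


@dataclass(frozen=True)
class AnovaResult:
    parameter: str
    effects: dict[str, EffectResult]


@dataclass(frozen=True)
class PosthocResult:
    contrast: str
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float
    t: float
    p: float
    df: int


def _cell_means(table: pd.DataFrame, parameter: str) -> pd.DataFrame:
    """Collapse to pianist x valence x category means over words.

    Missing (NaN) feature values -- degenerate improvisations such as
    single-attack pieces -- are imputed as the pianist's cell mean over the
    remaining words; the imputation count is logged.  An entirely empty cell
    is an incomplete design.
    """
    data = table[["pianist_id", "valence", "category", parameter]]
    n_missing = int(data[parameter].isna().sum())
    if n_missing:
        log.info("%s: imputing %d missing values with pianist-cell means", parameter, n_missing)
    cells = (
        data.groupby(["pianist_id", "valence", "category"], observed=True)[parameter]
        .mean()
        .unstack(["valence", "category"])
    )
    expected = {(v, c) for v in VALENCES for c in CATEGORIES}
    if set(cells.columns) != expected or cells.isna().any().any():
        raise IncompleteDesignError(
            f"{parameter}: every pianist needs data in all 4 valence x category cells"
        )
    return cells


def rm_anova_2x2(table: pd.DataFrame, parameter: str) -> AnovaResult:
    """Two-way repeated-measures ANOVA of one musical dimension.

    ``table`` is a long feature table (one row per improvisation) with
    ``pianist_id``, ``valence``, ``category`` and the feature column.
    Returns F, p and degrees of freedom for the valence and category main
    effects and their interaction.
    """
    cells = _cell_means(table, parameter)
    n = len(cells)
    # y[subject, valence, category] with fixed level order
    y = np.stack(
        [
            np.column_stack([cells[(v, c)].to_numpy() for c in CATEGORIES])
            for v in VALENCES
        ],
        axis=1,
    )
    grand = y.mean()
    m_v = y.mean(axis=(0, 2))          # per valence level
    m_c = y.mean(axis=(0, 1))          # per category level
    m_vc = y.mean(axis=0)              # valence x category
    m_s = y.mean(axis=(1, 2))          # per subject
    m_sv = y.mean(axis=2)              # subject x valence
    m_sc = y.mean(axis=1)              # subject x category

    ss_v = 2 * n * np.sum((m_v - grand) ** 2)
    ss_c = 2 * n * np.sum((m_c - grand) ** 2)
    ss_vc = n * np.sum((m_vc - m_v[:, None] - m_c[None, :] + grand) ** 2)
    ss_sv = 2 * np.sum((m_sv - m_s[:, None] - m_v[None, :] + grand) ** 2)
    ss_sc = 2 * np.sum((m_sc - m_s[:, None] - m_c[None, :] + grand) ** 2)
    ss_total = np.sum((y - grand) ** 2)
    ss_s = 4 * np.sum((m_s - grand) ** 2)
    ss_svc = ss_total - ss_v - ss_c - ss_vc - ss_s - ss_sv - ss_sc

    df_den = n - 1

    def effect(ss_effect: float, ss_error: float) -> EffectResult:
        ms_effect = ss_effect / 1
        ms_error = ss_error / df_den
        f = ms_effect / ms_error if ms_error > 0 else 0.0
        p = float(sps.f.sf(f, 1, df_den)) if ms_error > 0 else 1.0
        return EffectResult(F=float(f), p=p, df_num=1, df_den=df_den)

    return AnovaResult(
        parameter=parameter,
        effects={
            "valence": effect(ss_v, ss_sv),
            "category": effect(ss_c, ss_sc),
            "interaction": effect(ss_vc, ss_svc),
        },
    )


def rm_anova_valence_within(
    table: pd.DataFrame, parameter: str, category: str
) -> AnovaResult:
    """One-factor within-subject valence ANOVA restricted to one category."""
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    sub = table[table["category"] == category]
    data = sub[["pianist_id", "valence", parameter]]
    cells = (
        data.groupby(["pianist_id", "valence"], observed=True)[parameter]
        .mean()
        .unstack("valence")
    )
    if set(cells.columns) != set(VALENCES) or cells.isna().any().any():
        raise IncompleteDesignError(
            f"{parameter}: every pianist needs both valence cells in {category}"
        )
    n = len(cells)
    y = np.column_stack([cells[v].to_numpy() for v in VALENCES])
    grand = y.mean()
    m_v = y.mean(axis=0)
    m_s = y.mean(axis=1)
    ss_v = n * np.sum((m_v - grand) ** 2)
    ss_sv = np.sum((y - m_v[None, :] - m_s[:, None] + grand) ** 2)
    df_den = n - 1
    ms_error = ss_sv / df_den
    f = ss_v / ms_error if ms_error > 0 else 0.0
    p = float(sps.f.sf(f, 1, df_den)) if ms_error > 0 else 1.0
    return AnovaResult(
        parameter=parameter,
        effects={"valence": EffectResult(F=float(f), p=p, df_num=1, df_den=df_den)},
    )


def bonferroni_screen(p_values, n_tests: int | None = None) -> np.ndarray:
    """Family-wise screen: flag p < alpha / n_tests with alpha = 0.05.

    With the 12 musical dimensions this is the 0.05/12 = 0.0041... threshold.
    """
    p = np.asarray(p_values, dtype=float)
    n = n_tests if n_tests is not None else p.size
    if n < 1:
        raise ValueError("need n_tests >= 1")
    return p < 0.05 / n


def posthoc_paired_t(word_means_a, word_means_b, contrast: str = "") -> PosthocResult:
    """Paired t-test on word-level means (8 words per cell, paired by position).

    Degenerate pairings with zero difference variance are reported with
    infinite t (sign of the mean difference) and p = 0 rather than an error.
    """
    a = np.asarray(word_means_a, dtype=float)
    b = np.asarray(word_means_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-D lists")
    d = a - b
    n = len(d)
    sd = d.std(ddof=1)
    if sd == 0:
        t = 0.0 if d.mean() == 0 else math_copysign_inf(d.mean())
        p = 1.0 if d.mean() == 0 else 0.0
    else:
        t, p = sps.ttest_rel(a, b)
    return PosthocResult(
        contrast=contrast,
        mean_a=float(a.mean()),
        sem_a=float(sps.sem(a)),
        mean_b=float(b.mean()),
        sem_b=float(sps.sem(b)),
        t=float(t),
        p=float(p),
        df=n - 1,
    )


def math_copysign_inf(x: float) -> float:
    return float("inf") if x > 0 else float("-inf")


def word_cell_means(table: pd.DataFrame, parameter: str, valence: str, category: str) -> pd.Series:
    """Per-word means (across pianists) for one design cell, in word order."""
    sub = table[(table["valence"] == valence) & (table["category"] == category)]
    return sub.groupby("word", sort=False, observed=True)[parameter].mean()


def agreement_rates(response_table: pd.DataFrame, word_set=None) -> pd.DataFrame:
    """Per-word percent agreement of a word-classification control task.

    ``response_table`` has one row per subject x word with columns
    ``subject``, ``word``, ``assigned_valence``, ``assigned_category``.
    Returns per-word percent of subjects assigning the intended cell, plus the
    intended labels; the per-category mean error rate is 100 - mean agreement.
    """
    from .corpus_io import default_word_set

    word_set = word_set or default_word_set()
    intended = {e.word_en: (e.valence, e.category) for e in word_set}
    unknown_words = set(response_table["word"]) - set(intended)
    if unknown_words:
        raise ValueError(f"unknown words {sorted(unknown_words)[:5]}")
    valid_v, valid_c = set(VALENCES), set(CATEGORIES)
    bad = (~response_table["assigned_valence"].isin(valid_v)) | (
        ~response_table["assigned_category"].isin(valid_c)
    )
    if bad.any():
        raise ValueError("unknown category labels in responses")

    rows = []
    for word, group in response_table.groupby("word", sort=False):
        v, c = intended[word]
        correct = (group["assigned_valence"] == v) & (group["assigned_category"] == c)
        rows.append(
            {
                "word": word,
                "valence": v,
                "category": c,
                "agreement_pct": 100.0 * correct.mean(),
                "n_subjects": len(group),
            }
        )
    return pd.DataFrame(rows)


def category_error_rates(per_word: pd.DataFrame) -> pd.Series:
    """Mean percent error per (valence, category) cell from per-word agreement."""
    return 100.0 - per_word.groupby(["valence", "category"], observed=True)["agreement_pct"].mean()


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------


def anova_screen(table: pd.DataFrame, parameters=FEATURE_NAMES) -> pd.DataFrame:
    """ANOVA table for all parameters: F and p per effect, plus the
    Bonferroni flag on the family of tested parameters."""
    rows = []
    for param in parameters:
        res = rm_anova_2x2(table, param)
        row = {"parameter": param}
        for eff in EFFECTS:
            row[f"F_{eff}"] = res.effects[eff].F
            row[f"p_{eff}"] = res.effects[eff].p
        rows.append(row)
    out = pd.DataFrame(rows)
    for eff in EFFECTS:
        out[f"sig_{eff}"] = bonferroni_screen(out[f"p_{eff}"], len(parameters))
    return out


def valence_within_screen(table: pd.DataFrame, parameters=FEATURE_NAMES) -> pd.DataFrame:
    """Valence ANOVA restricted to each category, per parameter."""
    rows = []
    for param in parameters:
        row = {"parameter": param}
        for cat in CATEGORIES:
            res = rm_anova_valence_within(table, param, cat)
            row[f"F_{cat}"] = res.effects["valence"].F
            row[f"p_{cat}"] = res.effects["valence"].p
        rows.append(row)
    out = pd.DataFrame(rows)
    for cat in CATEGORIES:
        out[f"sig_{cat}"] = bonferroni_screen(out[f"p_{cat}"], len(parameters))
    return out


def posthoc_report(table: pd.DataFrame) -> dict:
    """The two post-hoc families: category contrasts on articulation within
    each valence, and valence contrasts on roughness within each category."""
    report = {}
    for valence in VALENCES:
        a = word_cell_means(table, "articulation", valence, "morality")
        b = word_cell_means(table, "articulation", valence, "logic")
        res = posthoc_paired_t(a.to_numpy(), b.to_numpy(), f"articulation {valence}: morality vs logic")
        report[res.contrast] = res.__dict__
    for category in CATEGORIES:
        a = word_cell_means(table, "roughness", "positive", category)
        b = word_cell_means(table, "roughness", "negative", category)
        res = posthoc_paired_t(a.to_numpy(), b.to_numpy(), f"roughness {category}: positive vs negative")
        report[res.contrast] = res.__dict__
    return report


def save_posthoc_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True))
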