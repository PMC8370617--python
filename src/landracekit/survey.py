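"""Farmer-knowledge (key-informant) survey analysis.

Each collected landrace carries up to three ranked uses and a set of 0-5
ordinal trait scores (0 = "don't know", 1 = very bad ... 5 = very good),
plus respondent profile fields.  The analyses here reproduce the standard
summaries: use classification (fresh / dual / flour / unknown), score
distributions, inter-trait Pearson correlations and respondent profiles.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io import SURVEY_SCORE_COLUMNS

TRAITS = SURVEY_SCORE_COLUMNS

USE_COLUMNS = ("use_primary", "use_secondary", "use_tertiary")

#: Free-text use vocabulary -> controlled tokens.
USE_SYNONYMS = {
    "fresh_consumption": "fresh_consumption",
    "fresh": "fresh_consumption",
    "household food roots": "fresh_consumption",
    "flour_processing": "flour_processing",
    "flour": "flour_processing",
    "processing": "flour_processing",
    "household food processed": "flour_processing",
}

USE_CLASSES = ("fresh", "dual", "flour", "unknown")


def round_half_up(x: float, ndigits: int = 0) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def normalize_use(use) -> str | None:
    if use is None or (isinstance(use, float) and np.isnan(use)):
        return None
    s = str(use).strip().lower()
    return USE_SYNONYMS.get(s, s) if s else None


def classify_use(uses) -> str:
    """Classify a ranked use list into fresh / dual / flour / unknown.

    "Dual purpose" means fresh consumption and flour processing both appear
    anywhere among the primary/secondary/tertiary uses; fresh or flour alone
    classify accordingly; neither mentioned is unknown.  The rank order is
    irrelevant to the class.
    """
    tokens = {normalize_use(u) for u in uses}
    fresh = "fresh_consumption" in tokens
    flour = "flour_processing" in tokens
    if fresh and flour:
        return "dual"
    if fresh:
        return "fresh"
    if flour:
        return "flour"
    return "unknown"


def classify_uses_table(table: pd.DataFrame) -> pd.Series:
    cols = [c for c in USE_COLUMNS if c in table.columns]
    if not cols:
        raise ValidationError(f"survey table lacks use columns {USE_COLUMNS}")
    return table[cols].apply(lambda row: classify_use(row.tolist()), axis=1)


def use_distribution(table: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages of landraces per use class."""
    if table.empty:
        raise ValidationError("empty survey table")
    classes = classify_uses_table(table)
    counts = classes.value_counts().reindex(USE_CLASSES, fill_value=0)
    total = int(counts.sum())
    pct = 100.0 * counts / total
    return pd.DataFrame(
        {
            "count": counts,
            "pct": pct,
            "pct_rounded": [round_half_up(v) for v in pct],
        }
    )


def score_distribution(table: pd.DataFrame, trait: str) -> pd.Series:
    """Counts of scores 0-5 for one trait; 0 is the "don't know" code."""
    if table.empty:
        raise ValidationError("empty survey table")
    if trait not in TRAITS or trait not in table.columns:
        raise ValidationError(f"unknown trait {trait!r}; expected one of {TRAITS}")
    scores = pd.to_numeric(table[trait], errors="raise")
    counts = scores.value_counts().reindex(range(6), fill_value=0).astype(int)
    counts.index.name = "score"
    if int(counts.sum()) != len(table):
        raise ValidationError(f"trait {trait} has values outside 0-5 or missing entries")
    return counts


def trait_correlation(
    table: pd.DataFrame,
    trait_a: str,
    trait_b: str,
    dont_know_policy: str = "exclude",
) -> tuple[float, float]:
    """Pearson R (and R^2) between two trait scores.

    The default policy treats 0 ("don't know") as missing and correlates
    pairwise-complete records; ``dont_know_policy="include"`` keeps the
    zeros as numeric scores.
    """
    if dont_know_policy not in ("exclude", "include"):
        raise ValueError("dont_know_policy must be 'exclude' or 'include'")
    for t in (trait_a, trait_b):
        if t not in TRAITS or t not in table.columns:
            raise ValidationError(f"unknown trait {t!r}")
    a = pd.to_numeric(table[trait_a], errors="raise").astype(float)
    b = pd.to_numeric(table[trait_b], errors="raise").astype(float)
    if dont_know_policy == "exclude":
        a = a.replace(0.0, np.nan)
        b = b.replace(0.0, np.nan)
    ok = a.notna() & b.notna()
    if int(ok.sum()) < 3:
        raise ValidationError("fewer than 3 complete pairs after the don't-know policy")
    r = float(stats.pearsonr(a[ok], b[ok]).statistic)
    return r, r * r


def trait_correlation_matrix(
    table: pd.DataFrame, traits=None, dont_know_policy: str = "exclude"
) -> pd.DataFrame:
    traits = list(traits) if traits is not None else [t for t in TRAITS if t in table.columns]
    out = pd.DataFrame(1.0, index=traits, columns=traits)
    for i, a in enumerate(traits):
        for b in traits[i + 1 :]:
            r, _ = trait_correlation(table, a, b, dont_know_policy)
            out.loc[a, b] = out.loc[b, a] = r
    return out


# ---------------------------------------------------------------------------
# respondent profiles
# ---------------------------------------------------------------------------

LAND_BANDS = ("<1", "1-4.9", "5-9.9", ">=10", "not_stated")
YEARS_BANDS = ("<5", "5-19", "20-49", ">=50", "not_stated")


def _band_land(acres) -> str:
    if acres is None or (isinstance(acres, float) and np.isnan(acres)):
        return "not_stated"
    a = float(acres)
    if a < 1:
        return "<1"
    if a < 5:
        return "1-4.9"
    if a < 10:
        return "5-9.9"
    return ">=10"


def _band_years(years) -> str:
    if years is None or (isinstance(years, float) and np.isnan(years)):
        return "not_stated"
    y = float(years)
    if y < 5:
        return "<5"
    if y < 20:
        return "5-19"
    if y < 50:
        return "20-49"
    return ">=50"


def _pct_of_total(counts: pd.Series, total: int) -> dict:
    return {str(k): round_half_up(100.0 * v / total, 1) for k, v in counts.items()}


def profile_summary(table: pd.DataFrame) -> dict:
    """Respondent-profile percentages: gender, education, land and years bands,
    growing trends and seed sources.

    When a ``respondent_id`` column exists, rows are deduplicated to one per
    respondent first (the survey table is otherwise one row per landrace).
    Land-size and years-growing percentages include a "not_stated" category;
    gender and education are percentages of stated responses.
    """
    if table.empty:
        raise ValidationError("empty survey table")
    t = table
    if "respondent_id" in t.columns:
        t = t.drop_duplicates(subset="respondent_id")
    n = len(t)
    out: dict = {"n_respondents": n}
    if "gender" in t.columns:
        g = t["gender"].dropna()
        out["gender_pct"] = _pct_of_total(g.value_counts(), len(g))
    if "education" in t.columns:
        e = t["education"].dropna()
        out["education_pct"] = _pct_of_total(e.value_counts(), len(e))
    if "land_acres" in t.columns:
        bands = t["land_acres"].map(_band_land).value_counts().reindex(LAND_BANDS, fill_value=0)
        out["land_pct"] = _pct_of_total(bands, n)
    if "years_growing" in t.columns:
        bands = (
            t["years_growing"].map(_band_years).value_counts().reindex(YEARS_BANDS, fill_value=0)
        )
        out["years_growing_pct"] = _pct_of_total(bands, n)
    for col in ("growing_trend", "seed_source"):
        if col in t.columns:
            v = t[col].dropna()
            out[f"{col}_pct"] = _pct_of_total(v.value_counts(), len(v))
    return out
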