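"""Morphometric discrimination chain for the two cherry-aphid subspecies.

Pearson correlation filter against body length, forward stepwise
Wilks'-Lambda discriminant analysis with per-character contribution
statistics, canonical variates, a two-group Fisher discriminant fit, the
published three-character identification key, and train/hold-out
classification summaries.

Conventions fixed here (the originating commercial package's defaults
where the source is silent): F-to-enter = 1.0, F-to-remove = 0.0;
Pearson p-values via the exact t transform with n-2 df, two-sided, no
multiple-testing correction; group covariances pooled (equal-covariance
discriminant); a key score of exactly zero is reported as indeterminate
rather than forced to either subspecies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import (
    CHARACTERS,
    LDF_CHARACTERS,
    LDF_COEFFICIENTS,
    LDF_INTERCEPT,
)

META_COLUMNS = ["individual_id", "sample_id", "host", "taxon", "role"]


class MorphTableError(ValueError):
    pass


def validate_morph_table(df: pd.DataFrame) -> None:
    missing = [c for c in META_COLUMNS + CHARACTERS if c not in df.columns]
    if missing:
        raise MorphTableError(f"morph table missing columns: {missing}")
    if (df[CHARACTERS] <= 0).any().any():
        bad = [c for c in CHARACTERS if (df[c] <= 0).any()]
        raise MorphTableError(f"non-positive measurements in: {bad}")


def write_morph_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_morph_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    validate_morph_table(df)
    return df


# ---------------------------------------------------------------------------
# Correlation filter
# ---------------------------------------------------------------------------

@dataclass
class CharCorrelation:
    character: str
    r: float
    t: float
    p: float
    removed: bool
    note: str = ""


@dataclass
class CorrelationReport:
    entries: list[CharCorrelation]
    threshold: float
    alpha: float

    @property
    def removed(self) -> list[str]:
        return [e.character for e in self.entries if e.removed]

    @property
    def retained(self) -> list[str]:
        return [e.character for e in self.entries if not e.removed]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"character": e.character, "r": e.r, "t": e.t, "p": e.p,
                 "removed": e.removed, "note": e.note}
                for e in self.entries
            ]
        )


def correlation_filter(
    df: pd.DataFrame, threshold: float = 0.70, alpha: float = 0.05
) -> CorrelationReport:
    """Remove characters strongly correlated with body length.

    A character is removed iff |r| >= threshold AND its two-sided p-value
    (t = r * sqrt((n-2)/(1-r^2)), n-2 df) is below alpha. Body length
    itself has r = 1 and is always removed. Zero-variance characters have
    undefined r and are retained with a warning note.
    """
    n = len(df)
    if n < 3:
        raise MorphTableError("correlation filter requires >= 3 records")
    bl = df["BL"].to_numpy(dtype=float)
    entries: list[CharCorrelation] = []
    for c in CHARACTERS:
        x = df[c].to_numpy(dtype=float)
        if c == "BL":
            entries.append(CharCorrelation(c, 1.0, float("inf"), 0.0, True))
            continue
        if np.ptp(x) == 0 or np.ptp(bl) == 0:
            entries.append(
                CharCorrelation(c, float("nan"), float("nan"), float("nan"),
                                False, "zero variance; r undefined")
            )
            continue
        r = float(np.corrcoef(x, bl)[0, 1])
        if abs(r) >= 1.0:
            t, p = float("inf"), 0.0
        else:
            t = r * np.sqrt((n - 2) / (1.0 - r * r))
            p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
        # boundary comparison tolerates float rounding: a character whose
        # realised correlation is the threshold itself must be removed
        removed = abs(r) >= threshold - 1e-9 and p < alpha
        entries.append(CharCorrelation(c, r, float(t), float(p), removed))
    return CorrelationReport(entries, threshold, alpha)


# ---------------------------------------------------------------------------
# Wilks'-Lambda machinery
# ---------------------------------------------------------------------------

def _scatter_matrices(X: np.ndarray, groups: np.ndarray):
    """Total and within-group cross-product (scatter) matrices."""
    grand = X.mean(axis=0)
    Xc = X - grand
    T = Xc.T @ Xc
    W = np.zeros_like(T)
    for g in np.unique(groups):
        Xg = X[groups == g]
        Xgc = Xg - Xg.mean(axis=0)
        W += Xgc.T @ Xgc
    return T, W


def _wilks_lambda(X: np.ndarray, groups: np.ndarray) -> float:
    T, W = _scatter_matrices(X, groups)
    det_t = np.linalg.det(T)
    det_w = np.linalg.det(W)
    if det_t <= 0:
        raise np.linalg.LinAlgError("singular total scatter matrix")
    return float(det_w / det_t)


def _tolerance(X_model: np.ndarray, x: np.ndarray) -> float:
    """1 - R^2 of x regressed on the in-model characters (collinearity
    guard)."""
    if X_model.shape[1] == 0:
        return 1.0
    A = np.column_stack([np.ones(len(x)), X_model])
    coef, *_ = np.linalg.lstsq(A, x, rcond=None)
    resid = x - A @ coef
    ss_tot = float(((x - x.mean()) ** 2).sum())
    if ss_tot == 0:
        return 0.0
    return max(float((resid ** 2).sum() / ss_tot), 0.0)


@dataclass
class StepRow:
    character: str
    wilks_lambda: float        # Lambda of the model with this character removed
    partial_lambda: float      # Lambda_with / Lambda_without
    f_remove: float
    p_level: float
    tolerance: float
    one_minus_tolerance: float


@dataclass
class StepRecord:
    step: int
    entered: str
    lambda_after: float
    f_enter: float
    rows: list[StepRow]


@dataclass
class StepwiseTrace:
    steps: list[StepRecord]
    inclusion_order: list[str]
    final_lambda: float
    n: int
    n_groups: int

    def final_table(self) -> pd.DataFrame:
        """Per-character contribution table for the final model, ordered
        by F-remove descending (the published presentation order)."""
        rows = self.steps[-1].rows if self.steps else []
        df = pd.DataFrame(
            [
                {"character": r.character, "wilks_lambda": r.wilks_lambda,
                 "partial_lambda": r.partial_lambda, "f_remove": r.f_remove,
                 "p_level": r.p_level, "tolerance": r.tolerance,
                 "one_minus_tolerance": r.one_minus_tolerance}
                for r in rows
            ]
        )
        if not df.empty:
            df = df.sort_values("f_remove", ascending=False).reset_index(drop=True)
        return df


_TOLERANCE_FLOOR = 1e-6


def stepwise_wilks(
    df: pd.DataFrame,
    characters: list[str],
    group_col: str = "sample_id",
    f_enter: float = 1.0,
    f_remove: float = 0.0,
) -> StepwiseTrace:
    """Forward stepwise discriminant analysis on Wilks' Lambda.

    At each step the candidate with the largest F-to-enter (equivalently
    the largest Lambda reduction) joins the model if F >= f_enter;
    in-model characters with F-to-remove < f_remove would be dropped
    (never, under the default 0). For each in-model character the trace
    records Lambda-if-removed, partial Lambda, F-remove with
    (g-1, n-g-p+1) df, its p-level and the tolerance (1 - R^2 against
    the other in-model characters).
    """
    groups = df[group_col].to_numpy()
    uniq = np.unique(groups)
    g = len(uniq)
    n = len(df)
    if g < 2:
        raise MorphTableError("stepwise analysis requires >= 2 groups")
    if n <= g + len(characters):
        raise MorphTableError(
            f"too few records (n={n}) for {g} groups and "
            f"{len(characters)} characters"
        )
    X_all = df[characters].to_numpy(dtype=float)

    # collinearity screen on the full candidate set
    _, W_all = _scatter_matrices(X_all, groups)
    diag = np.sqrt(np.diag(W_all))
    if (diag == 0).any():
        bad = [characters[i] for i in np.where(diag == 0)[0]]
        raise np.linalg.LinAlgError(
            f"singular within-group covariance; zero-variance characters: {bad}"
        )

    model: list[int] = []
    steps: list[StepRecord] = []
    step_no = 0
    while True:
        p = len(model)
        lam_cur = _wilks_lambda(X_all[:, model], groups) if model else 1.0
        best_idx, best_f, best_lam = None, -np.inf, None
        for j in range(len(characters)):
            if j in model:
                continue
            tol = _tolerance(X_all[:, model], X_all[:, j])
            if tol < _TOLERANCE_FLOOR:
                continue
            try:
                lam_new = _wilks_lambda(X_all[:, model + [j]], groups)
            except np.linalg.LinAlgError:
                continue
            if lam_new <= 0:
                continue
            f_stat = ((n - g - p) / (g - 1)) * (lam_cur / lam_new - 1.0)
            if f_stat > best_f + 1e-12:
                best_f, best_idx, best_lam = f_stat, j, lam_new
        if best_idx is None or best_f < f_enter:
            break
        model.append(best_idx)
        step_no += 1
        p = len(model)
        rows = []
        for j in model:
            others = [k for k in model if k != j]
            lam_without = (
                _wilks_lambda(X_all[:, others], groups) if others else 1.0
            )
            partial = best_lam / lam_without
            df2 = n - g - p + 1
            f_rm = (df2 / (g - 1)) * (lam_without / best_lam - 1.0)
            p_level = float(stats.f.sf(f_rm, g - 1, df2)) if df2 > 0 else float("nan")
            tol = _tolerance(X_all[:, others], X_all[:, j])
            rows.append(
                StepRow(characters[j], float(lam_without), float(partial),
                        float(f_rm), p_level, float(tol), float(1 - tol))
            )
        steps.append(
            StepRecord(step_no, characters[model[-1]], float(best_lam),
                       float(best_f), rows)
        )
        # backward check (never triggers at the default f_remove = 0)
        worst = min(rows, key=lambda r: r.f_remove)
        if worst.f_remove < f_remove and len(model) > 1:
            model.remove(characters.index(worst.character))

    final_lambda = _wilks_lambda(X_all[:, model], groups) if model else 1.0
    return StepwiseTrace(
        steps=steps,
        inclusion_order=[characters[j] for j in model],
        final_lambda=float(final_lambda),
        n=n,
        n_groups=g,
    )


# ---------------------------------------------------------------------------
# Canonical variates
# ---------------------------------------------------------------------------

@dataclass
class CanonicalModel:
    characters: list[str]
    eigenvalues: np.ndarray
    coefficients: np.ndarray  # (n_chars, n_variates), unit pooled within-var
    grand_mean: np.ndarray
    group_scores: pd.DataFrame  # group -> mean scores on each variate

    def scores(self, df: pd.DataFrame) -> np.ndarray:
        X = df[self.characters].to_numpy(dtype=float)
        return (X - self.grand_mean) @ self.coefficients


def canonical_variates(
    df: pd.DataFrame, characters: list[str], group_col: str = "sample_id"
) -> CanonicalModel:
    """Canonical discriminant axes: eigenvectors of W^-1 B scaled to unit
    pooled within-group variance, eigenvalues non-increasing."""
    from scipy.linalg import eigh

    groups = df[group_col].to_numpy()
    uniq = sorted(np.unique(groups))
    g = len(uniq)
    n = len(df)
    X = df[characters].to_numpy(dtype=float)
    T, W = _scatter_matrices(X, groups)
    B = T - W
    try:
        evals, evecs = eigh(B, W)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"singular within-group scatter for characters {characters}"
        ) from exc
    order = np.argsort(evals)[::-1]
    k = min(g - 1, len(characters))
    evals = np.clip(evals[order][:k], 0.0, None)
    # eigh normalises v' W v = 1; rescale so v' (W/(n-g)) v = 1
    V = evecs[:, order][:, :k] * np.sqrt(n - g)
    grand = X.mean(axis=0)
    scores = (X - grand) @ V
    rows = {}
    for grp in uniq:
        rows[grp] = scores[groups == grp].mean(axis=0)
    group_scores = pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"CV{i + 1}" for i in range(k)]
    )
    group_scores.index.name = group_col
    return CanonicalModel(
        characters=list(characters),
        eigenvalues=evals,
        coefficients=V,
        grand_mean=grand,
        group_scores=group_scores,
    )


# ---------------------------------------------------------------------------
# Two-group discriminant and the identification key
# ---------------------------------------------------------------------------

@dataclass
class LinearKey:
    """Linear discriminant key: score = sum(coef * character) + intercept;
    score > 0 -> cerasi, score < 0 -> pruniavium, 0 -> indeterminate."""

    coefficients: dict[str, float]
    intercept: float
    provenance: str = "fitted"

    def score(self, values) -> float:
        missing = [c for c in self.coefficients if c not in values]
        if missing:
            raise KeyError(f"missing characters for key: {missing}")
        return float(
            sum(w * float(values[c]) for c, w in self.coefficients.items())
            + self.intercept
        )

    def direction(self) -> np.ndarray:
        return np.array(list(self.coefficients.values()))


#: The published identification key at full precision.
PRINTED_KEY = LinearKey(
    coefficients=dict(zip(LDF_CHARACTERS, LDF_COEFFICIENTS)),
    intercept=LDF_INTERCEPT,
    provenance="printed",
)


def fit_two_group_ldf(
    df: pd.DataFrame,
    characters: tuple[str, ...] = LDF_CHARACTERS,
    role: str | None = "train",
) -> LinearKey:
    """Fisher two-group discriminant (pooled covariance, equal priors)
    between the subspecies, boundary at score = 0, cerasi positive."""
    sub = df if role is None else df[df["role"] == role]
    taxa = set(sub["taxon"])
    if not {"cerasi", "pruniavium"} <= taxa:
        raise MorphTableError(
            f"both taxa required in the training data, found {sorted(taxa)}"
        )
    Xc = sub.loc[sub["taxon"] == "cerasi", list(characters)].to_numpy(float)
    Xp = sub.loc[sub["taxon"] == "pruniavium", list(characters)].to_numpy(float)
    mu_c, mu_p = Xc.mean(axis=0), Xp.mean(axis=0)
    Sc = np.cov(Xc, rowvar=False, ddof=1)
    Sp = np.cov(Xp, rowvar=False, ddof=1)
    nc, np_ = len(Xc), len(Xp)
    pooled = ((nc - 1) * Sc + (np_ - 1) * Sp) / (nc + np_ - 2)
    try:
        w = np.linalg.solve(pooled, mu_c - mu_p)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"singular pooled covariance for characters {characters}"
        ) from exc
    b = -0.5 * float(w @ (mu_c + mu_p))
    if float(w @ mu_c) + b < 0:  # orient cerasi positive
        w, b = -w, -b
    return LinearKey(dict(zip(characters, map(float, w))), float(b), "fitted")


def apply_key(data, key: LinearKey = PRINTED_KEY) -> pd.DataFrame:
    """Score records with a key and assign by sign.

    Accepts a morph table (DataFrame) or a single record mapping. Returns
    a DataFrame with score and assignment; a record missing a key
    character gets an 'error' assignment naming the character.
    """
    if isinstance(data, dict):
        records = [data]
        index = [0]
    else:
        records = data.to_dict("records")
        index = list(data.index)
    rows = []
    for rec in records:
        try:
            s = key.score(rec)
        except KeyError as exc:
            rows.append({"score": float("nan"), "assignment": "error",
                         "error": str(exc)})
            continue
        if s > 0:
            a = "cerasi"
        elif s < 0:
            a = "pruniavium"
        else:
            a = "indeterminate"
        rows.append({"score": s, "assignment": a, "error": ""})
    return pd.DataFrame(rows, index=index)


# ---------------------------------------------------------------------------
# Classification summaries
# ---------------------------------------------------------------------------

@dataclass
class TaxonSummary:
    taxon: str
    n: int
    n_correct: int
    percent: float


@dataclass
class ClassificationSummary:
    per_taxon: list[TaxonSummary]
    overall_n: int
    overall_correct: int
    overall_percent: float

    def taxon(self, name: str) -> TaxonSummary:
        for t in self.per_taxon:
            if t.taxon == name:
                return t
        raise KeyError(name)

    def as_dict(self) -> dict:
        return {
            "per_taxon": {
                t.taxon: {"n": t.n, "n_correct": t.n_correct,
                          "percent": t.percent}
                for t in self.per_taxon
            },
            "overall": {"n": self.overall_n,
                        "n_correct": self.overall_correct,
                        "percent": self.overall_percent},
        }


def classification_summary(
    assignments: pd.DataFrame, truth: pd.Series
) -> ClassificationSummary:
    """Per-taxon and overall percent correct, reported to 2 decimals
    (the published reporting style for identification rates)."""
    if not assignments.index.equals(truth.index):
        raise MorphTableError("assignment and truth ids do not align")
    per = []
    total_n = total_c = 0
    for taxon in sorted(truth.unique()):
        mask = truth == taxon
        n = int(mask.sum())
        correct = int((assignments.loc[mask, "assignment"] == taxon).sum())
        pct = round(100.0 * correct / n, 2) if n else float("nan")
        per.append(TaxonSummary(taxon, n, correct, pct))
        total_n += n
        total_c += correct
    overall = round(100.0 * total_c / total_n, 2) if total_n else float("nan")
    return ClassificationSummary(per, total_n, total_c, overall)


def holdout_validation(
    df: pd.DataFrame, key: LinearKey = PRINTED_KEY
) -> ClassificationSummary:
    """Apply a key to hold-out individuals and summarise correctness."""
    hold = df[df["role"] == "holdout"]
    if hold.empty:
        return ClassificationSummary([], 0, 0, float("nan"))
    assign = apply_key(hold, key)
    return classification_summary(assign, hold["taxon"])


def sample_mean_ldf_table(
    df: pd.DataFrame, key: LinearKey = PRINTED_KEY, role: str = "holdout"
) -> pd.DataFrame:
    """Per-sample mean key score against mean body length (scatter-plot
    data product for the hold-out samples)."""
    sub = df[df["role"] == role].copy()
    sub["ldf_score"] = apply_key(sub, key)["score"].to_numpy()
    out = (
        sub.groupby(["sample_id", "host", "taxon"], as_index=False)
        .agg(mean_ldf=("ldf_score", "mean"), mean_bl=("BL", "mean"),
             n=("individual_id", "count"))
        .sort_values("sample_id")
        .reset_index(drop=True)
    )
    return out
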