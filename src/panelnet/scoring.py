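"""Scale scoring, reliability, and descriptive group statistics.

Turns item-level questionnaire responses into the composite variables the
networks consume:

* ``irr``    -- child irritability: mean of 3 CBCL items (0-2 scale),
* ``nVio``   -- non-violent discipline (CTSPC, 4 items, frequency 0-6),
  reverse-coded so higher = fewer non-violent-discipline occurrences,
* ``psyAgg`` -- psychological aggression (CTSPC, 5 items),
* ``phyAs``  -- physical assault (CTSPC, 5 items),
* ``neg``    -- neglect (CTSPC, 5 items),
* ``pstr``   -- parenting stress: mean of 4 Aggravation-in-Parenting
  items (1-4), items reverse-coded so higher = more stress,
* ``cAtt``, ``cPra`` -- single-item cultural attachment / practice (1-4),
  measured once at baseline and carried as time-invariant variables.

CTSPC raw codes 1-6 are frequency categories; 7 ("not in the past year")
and 8 ("never happened") are recoded to 0.  Reliability is McDonald's
omega from a one-factor maximum-likelihood fit (no tau-equivalence
assumed) for multi-item scales, and the Spearman-Brown corrected
split-half correlation for the two-item cultural pair.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

log = logging.getLogger("panelnet")

__all__ = [
    "recode_ctspc",
    "reverse_code",
    "score_composite",
    "mcdonalds_omega",
    "omega_from_cov",
    "split_half_spearman_brown",
    "describe_by_group",
    "pearson_matrix",
    "score_items",
    "items_from_wide",
    "reliability_report",
    "OmegaResult",
    "SCALES",
]

# scale id -> (instrument, item count, composite bounds, item bounds)
SCALES = {
    "irr": ("CBCL_IRR", 3, (0, 2), (0, 2)),
    "nVio": ("CTSPC", 4, (0, 6), (0, 6)),
    "psyAgg": ("CTSPC", 5, (0, 6), (0, 6)),
    "phyAs": ("CTSPC", 5, (0, 6), (0, 6)),
    "neg": ("CTSPC", 5, (0, 6), (0, 6)),
    "pstr": ("APS", 4, (1, 4), (1, 4)),
}


class ScoringError(ValueError):
    pass


def recode_ctspc(raw_code: int) -> int:
    """CTSPC frequency recode: 1-6 unchanged, 0/7/8 -> 0.

    Codes 7 ("not in the past year, but it happened before") and 8 ("this
    has never happened") denote zero past-year frequency.
    """
    code = int(raw_code)
    if code != raw_code or not 0 <= code <= 8:
        raise ScoringError(f"CTSPC raw code {raw_code!r} outside 0-8")
    return 0 if code in (0, 7, 8) else code


def reverse_code(score: float, lo: float, hi: float) -> float:
    """Reflect a score within its scale bounds: ``lo + hi - score``.

    An involution: applying it twice returns the input.
    """
    if not lo <= score <= hi:
        raise ScoringError(f"score {score} outside [{lo}, {hi}]")
    return lo + hi - score


def score_composite(items, min_items: int) -> float:
    """Mean of non-missing item scores, or NaN below ``min_items``."""
    arr = np.asarray(items, dtype=float)
    if arr.size == 0:
        log.warning("score_composite called with no items")
        return np.nan
    ok = ~np.isnan(arr)
    if ok.sum() < min_items:
        return np.nan
    return float(arr[ok].mean())


# ---------------------------------------------------------------------------
# reliability
# ---------------------------------------------------------------------------

@dataclass
class OmegaResult:
    omega: float
    loadings: np.ndarray
    uniquenesses: np.ndarray
    n_used: int
    converged: bool
    heywood: bool

    def __float__(self):
        return self.omega


def _fa_ml_discrepancy(x, S, p):
    lam = x[:p]
    theta = np.exp(x[p:])
    Sig = np.outer(lam, lam) + np.diag(theta)
    try:
        c = np.linalg.cholesky(Sig)
    except np.linalg.LinAlgError:
        return np.inf
    logdet = 2 * np.sum(np.log(np.diag(c)))
    cinv = np.linalg.solve(c, np.eye(p))
    return logdet + float(np.sum((cinv.T @ cinv) * S))


def mcdonalds_omega(item_matrix, min_n: int = 50) -> OmegaResult:
    """McDonald's omega from a one-factor ML fit on the item covariance.

    Fits ``Sigma = lambda lambda' + diag(theta)`` by maximum likelihood
    and returns ``(sum lambda)^2 / ((sum lambda)^2 + sum theta)``.
    Invariant to item reordering.  Non-convergence or a Heywood case
    (uniqueness at the boundary) is flagged in the result rather than
    silently clamped.
    """
    X = np.asarray(item_matrix, dtype=float)
    X = X[~np.isnan(X).any(axis=1)]
    n, p = X.shape
    if p < 3:
        raise ScoringError("omega needs >= 3 items (use split-half for 2)")
    if n < min_n:
        raise ScoringError(f"omega needs >= {min_n} complete rows, got {n}")
    S = np.cov(X, rowvar=False, ddof=1)
    return omega_from_cov(S, n_used=n)


def omega_from_cov(S, n_used: int = 0) -> OmegaResult:
    """Omega from an item covariance matrix (one-factor ML fit)."""
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    sd = np.sqrt(np.diag(S))
    if np.any(sd < 1e-12):
        raise ScoringError("constant item; omega undefined")
    # start from first principal component
    w, V = np.linalg.eigh(S)
    lam0 = V[:, -1] * np.sqrt(max(w[-1], 1e-6))
    if lam0.sum() < 0:
        lam0 = -lam0
    th0 = np.clip(np.diag(S) - lam0**2, 1e-3, None)
    x0 = np.concatenate([lam0, np.log(th0)])
    res = optimize.minimize(_fa_ml_discrepancy, x0, args=(S, p),
                            method="L-BFGS-B",
                            options={"maxiter": 1000, "ftol": 1e-14})
    lam = res.x[:p]
    if lam.sum() < 0:
        lam = -lam
    theta = np.exp(res.x[p:])
    heywood = bool(np.any(theta < 1e-6 * np.diag(S)))
    omega = float(lam.sum() ** 2 / (lam.sum() ** 2 + theta.sum()))
    if heywood:
        warnings.warn("Heywood case in omega fit (uniqueness ~ 0)",
                      stacklevel=2)
    return OmegaResult(omega, lam, theta, n_used, bool(res.success), heywood)


def split_half_spearman_brown(x1, x2) -> float:
    """Spearman-Brown corrected split-half reliability, ``2r / (1 + r)``.

    ``r`` is the Pearson correlation of the paired halves.  A negative
    correlation yields a flagged (warned) negative value rather than a
    silent clamp.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    ok = ~(np.isnan(x1) | np.isnan(x2))
    if ok.sum() < 10:
        raise ScoringError("need >= 10 paired observations")
    a, b = x1[ok], x2[ok]
    if a.std() < 1e-12 or b.std() < 1e-12:
        raise ScoringError("zero variance in a half; reliability undefined")
    r = float(np.corrcoef(a, b)[0, 1])
    if r < 0:
        warnings.warn(f"negative split-half correlation ({r:.3f})",
                      stacklevel=2)
    return 2 * r / (1 + r)


# ---------------------------------------------------------------------------
# item table -> score table
# ---------------------------------------------------------------------------

def score_items(items: pd.DataFrame, *, min_items: dict | None = None,
                require_all: bool = True) -> pd.DataFrame:
    """Score a long item table into a per-person-per-wave composite table.

    ``items`` columns: person_id, group, wave, instrument, item_id,
    raw_code (NaN = missing).  CTSPC codes are frequency-recoded; nVio is
    reverse-coded at the composite level; APS items are reverse-coded
    before averaging.  Cultural items (wave 0) propagate to all waves as
    cAtt / cPra.  By default all items of a scale are required
    (missing-item prorating changes composite variance); pass
    ``min_items`` to relax per scale.
    """
    items = items.copy()
    need = {"person_id", "group", "wave", "instrument", "item_id",
            "raw_code"}
    if not need.issubset(items.columns):
        raise ScoringError(f"item table missing columns {need - set(items.columns)}")
    dup = items.duplicated(["person_id", "wave", "item_id"])
    if dup.any():
        raise ScoringError("duplicate (person, wave, item) records")

    # item_id convention: "<scale>_<k>" for multi-item scales, cAtt/cPra
    def scale_of(row_item):
        return row_item.rsplit("_", 1)[0]

    items["scale"] = items["item_id"].map(scale_of)
    waves = sorted(w for w in items["wave"].unique() if w != 0)
    recs = []
    cult = items[items["wave"] == 0]
    cult_map = cult.pivot_table(index="person_id", columns="item_id",
                                values="raw_code", aggfunc="first")
    groups = items.groupby("person_id")["group"].first()

    mi = dict(min_items or {})
    for (pid, wave), sub in items[items["wave"] != 0].groupby(
            ["person_id", "wave"]):
        row = {"person_id": pid, "group": groups[pid], "wave": wave}
        for scale, (instr, k, cb, ib) in SCALES.items():
            vals = sub.loc[sub["scale"] == scale, "raw_code"].to_numpy(float)
            scored = np.full(k, np.nan)
            for i, v in enumerate(vals[:k]):
                if np.isnan(v):
                    continue
                if instr == "CTSPC":
                    scored[i] = recode_ctspc(v)
                elif instr == "APS":
                    scored[i] = reverse_code(v, 1, 4)
                else:
                    if not ib[0] <= v <= ib[1]:
                        raise ScoringError(
                            f"{scale} item code {v} outside {ib} "
                            f"(person {pid}, wave {wave})")
                    scored[i] = v
            comp = score_composite(scored, mi.get(scale, k if require_all
                                                  else 1))
            if scale == "nVio" and not np.isnan(comp):
                comp = reverse_code(comp, 0, 6)
            row[scale] = comp
        for cvar in ("cAtt", "cPra"):
            v = cult_map[cvar].get(pid, np.nan) if cvar in cult_map else np.nan
            # cultural items coded 1=strongly agree..4=strongly disagree;
            # reverse so higher = stronger belonging
            row[cvar] = reverse_code(v, 1, 4) if not np.isnan(v) else np.nan
        recs.append(row)
    cols = ["person_id", "group", "wave"] + list(SCALES) + ["cAtt", "cPra"]
    return pd.DataFrame.from_records(recs)[cols].sort_values(
        ["person_id", "wave"], ignore_index=True)


def items_from_wide(wide: pd.DataFrame) -> pd.DataFrame:
    """Convert a wide item table to the long layout ``score_items`` reads.

    Wide columns follow ``INSTRUMENT.item.wave`` (e.g.
    ``CTSPC.psyAgg_1.3``, ``CBCL_IRR.irr_2.5``, ``CULT.cAtt.0``) plus
    ``person_id`` and ``group``.
    """
    need = {"person_id", "group"}
    if not need.issubset(wide.columns):
        raise ScoringError("wide table needs person_id and group columns")
    recs = []
    for col in wide.columns:
        if col in need:
            continue
        parts = col.split(".")
        if len(parts) != 3:
            raise ScoringError(
                f"column {col!r} does not follow INSTRUMENT.item.wave")
        instrument, item_id, wave = parts
        recs.append(pd.DataFrame({
            "person_id": wide["person_id"], "group": wide["group"],
            "wave": int(wave), "instrument": instrument,
            "item_id": item_id, "raw_code": wide[col].to_numpy(float),
        }))
    if not recs:
        raise ScoringError("no item columns found")
    return pd.concat(recs, ignore_index=True)


def reliability_report(items: pd.DataFrame) -> list[dict]:
    """Omega per multi-item scale and wave; Spearman-Brown for cAtt/cPra."""
    items = items.copy()
    items["scale"] = items["item_id"].map(lambda s: s.rsplit("_", 1)[0])
    out = []
    for wave in sorted(w for w in items["wave"].unique() if w != 0):
        sub = items[items["wave"] == wave]
        for scale, (instr, k, cb, ib) in SCALES.items():
            mat = sub[sub["scale"] == scale].pivot_table(
                index="person_id", columns="item_id", values="raw_code",
                aggfunc="first")
            if mat.shape[1] != k:
                continue
            X = mat.to_numpy(float)
            if instr == "CTSPC":
                with np.errstate(invalid="ignore"):
                    X = np.where(np.isin(X, (0, 7, 8)), 0, X)
            try:
                res = mcdonalds_omega(X)
            except ScoringError as e:
                log.warning("omega failed for %s wave %s: %s", scale, wave, e)
                continue
            out.append({"scale": scale, "wave": int(wave),
                        "omega": res.omega, "n_used": res.n_used,
                        "converged": res.converged,
                        "heywood": res.heywood})
    cult = items[items["wave"] == 0].pivot_table(
        index="person_id", columns="item_id", values="raw_code",
        aggfunc="first")
    if {"cAtt", "cPra"}.issubset(cult.columns):
        try:
            sb = split_half_spearman_brown(cult["cAtt"], cult["cPra"])
            out.append({"scale": "cultural", "wave": 0, "split_half": sb,
                        "n_used": int(cult[["cAtt", "cPra"]]
                                      .dropna().shape[0])})
        except ScoringError as e:
            log.warning("split-half failed: %s", e)
    return out


# ---------------------------------------------------------------------------
# descriptives
# ---------------------------------------------------------------------------

def describe_by_group(scores: pd.DataFrame, variable: str,
                      wave: int) -> dict:
    """Group means/SDs plus a one-way ANOVA for one variable at one wave.

    Listwise per variable: persons missing the variable at the wave are
    dropped.  Groups with fewer than 2 observations are dropped with a
    warning; zero within-group variance is flagged.
    """
    sub = scores[scores["wave"] == wave][["group", variable]].dropna()
    rows, samples = [], []
    for g, s in sub.groupby("group", observed=True):
        x = s[variable].to_numpy(float)
        if len(x) < 2:
            warnings.warn(f"group {g} has < 2 observations; dropped",
                          stacklevel=2)
            continue
        rows.append({"group": g, "n": len(x), "mean": float(x.mean()),
                     "sd": float(x.std(ddof=1))})
        samples.append(x)
    if len(samples) < 2:
        raise ScoringError("ANOVA needs >= 2 groups with >= 2 observations")
    zero_within = all(np.var(x) < 1e-24 for x in samples)
    if zero_within:
        warnings.warn("zero within-group variance; F degenerate",
                      stacklevel=2)
        means = [x.mean() for x in samples]
        if np.ptp(means) > 0:
            F, pval = np.inf, 0.0
        else:
            F, pval = 0.0, 1.0
    else:
        F, pval = stats.f_oneway(*samples)
    return {"variable": variable, "wave": int(wave), "groups": rows,
            "F": float(F), "p": float(pval),
            "zero_within_variance": zero_within}


def pearson_matrix(scores: pd.DataFrame, wave: int,
                   variables: list[str] | None = None,
                   min_pairs: int = 3) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations of the score table at a wave.

    Entries with fewer than ``min_pairs`` complete pairs or a constant
    variable are NaN (flagged with a warning).
    """
    if variables is None:
        variables = [c for c in scores.columns
                     if c not in ("person_id", "group", "wave", "included")]
    sub = scores.loc[scores["wave"] == wave, variables]
    R = sub.corr(min_periods=min_pairs)
    if R.isna().to_numpy().any():
        warnings.warn("undefined correlation entries (constant variable or "
                      "too few pairs)", stacklevel=2)
    return R
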