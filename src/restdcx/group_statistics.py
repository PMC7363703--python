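"""Group-level statistics on per-subject efficiency values.

The battery mirrors a clinical case-control design: an eight-comparison
whole-brain registry (patients and clinically defined subgroups against
controls, plus two within-patient contrasts), the same registry per
resting-state network with Bonferroni correction over the seven networks,
Cohen's d effect sizes with the conventional magnitude labels, diagnostic
metrics against the 99th-percentile reference limit of the control group,
and rank correlations between whole-brain efficiency and clinical variables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientDataError, InvalidSpecError, UndefinedEffectError
from .parcellation import RSN_LABELS

#: (lower |d| edge, label); a value at or above an edge takes that label.
D_LABEL_EDGES = (
    (2.00, "huge"),
    (1.20, "very large"),
    (0.80, "large"),
    (0.50, "medium"),
    (0.20, "small"),
    (0.01, "very small"),
)

WHOLE_BRAIN_M = 8  # comparisons a..h
RSN_M = 7  # networks


def mann_whitney_u(x, y, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of x, p).

    ``mode='auto'`` uses the exact permutation null when the smaller sample
    has at most 8 observations and there are no ties, and the tie-corrected
    normal approximation with continuity correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InvalidSpecError("both samples must be non-empty")
    if mode not in ("auto", "exact", "asymptotic"):
        raise InvalidSpecError(f"unknown mode {mode!r}")
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    if mode == "auto":
        mode = "exact" if (min(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    if mode == "exact" and has_ties:
        mode = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=mode,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-corrected p-value: min(1, m·p)."""
    if not 0 <= p <= 1:
        raise InvalidSpecError("p must be in [0, 1]")
    if m < 1:
        raise InvalidSpecError("m must be >= 1")
    return min(1.0, m * p)


def label_effect_size(d: float) -> str:
    """Magnitude label for |d| on the conventional scale."""
    mag = abs(d)
    for edge, label in D_LABEL_EDGES:
        if mag >= edge:
            return label
    return "negligible"


def cohens_d(x, y) -> tuple[float, str]:
    """Cohen's d with pooled standard deviation, plus its magnitude label."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise InvalidSpecError("Cohen's d needs at least 2 observations per group")
    s1, s2 = np.var(x, ddof=1), np.var(y, ddof=1)
    pooled = np.sqrt(((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2))
    diff = float(np.mean(x) - np.mean(y))
    if pooled == 0:
        if diff == 0:
            return 0.0, "negligible"
        raise UndefinedEffectError("zero pooled SD with unequal means")
    d = diff / float(pooled)
    return d, label_effect_size(d)


@dataclass
class DiagnosticReport:
    """Confusion-matrix summary at the control-based reference limit.

    Rates are percentages; ``ppv`` is NaN when no subject tests positive.
    """

    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float


def diagnostic_metrics(patient_values, control_values, percentile: float = 99.0) -> DiagnosticReport:
    """Classify subjects against the ``percentile``-th percentile of controls.

    The threshold uses linear interpolation between order statistics; a
    subject is positive when its value is strictly greater than the
    threshold, so ties count as negative.
    """
    pat = np.asarray(patient_values, dtype=float)
    con = np.asarray(control_values, dtype=float)
    if pat.size == 0 or con.size == 0:
        raise InvalidSpecError("both groups must be non-empty")
    threshold = float(np.percentile(con, percentile, method="linear"))
    tp = int(np.sum(pat > threshold))
    fn = pat.size - tp
    fp = int(np.sum(con > threshold))
    tn = con.size - fp
    ppv = 100.0 * tp / (tp + fp) if (tp + fp) > 0 else float("nan")
    npv = 100.0 * tn / (tn + fn) if (tn + fn) > 0 else float("nan")
    return DiagnosticReport(
        threshold=threshold, tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=100.0 * tp / pat.size,
        specificity=100.0 * tn / con.size,
        ppv=ppv, npv=npv,
    )


def _exact_spearman_p(rho_obs: float, n: int) -> float:
    """Two-sided exact p for Spearman's rho under the permutation null
    (tie-free ranks, n <= 9)."""
    base = np.arange(1, n + 1)
    perms = np.array(list(permutations(base)), dtype=float)
    d2 = np.sum((perms - base) ** 2, axis=1)
    rhos = 1.0 - 6.0 * d2 / (n * (n**2 - 1))
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with exact p for small tie-free samples
    (n <= 9) and the t-approximation otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise InsufficientDataError("need at least 3 complete pairs")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        warnings.warn("constant variable: Spearman correlation undefined", stacklevel=2)
        return float("nan"), float("nan")
    rho = float(stats.spearmanr(x, y).statistic)
    tie_free = np.unique(x).size == n and np.unique(y).size == n
    if n <= 9 and tie_free:
        return rho, _exact_spearman_p(rho, n)
    return rho, float(stats.spearmanr(x, y).pvalue)


def pearson(x, y) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise InsufficientDataError("need at least 3 complete pairs")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


CLINICAL_VARIABLES = {"onset": "onset_age", "duration": "duration", "ilae": "ilae"}


def clinical_correlations(
    values: pd.Series, clinical: pd.DataFrame, method: str = "spearman"
) -> pd.DataFrame:
    """Correlate per-patient efficiency with onset age, disease duration and
    ILAE outcome. ``values`` must be indexed like ``clinical`` (one row per
    patient); missing covariates are dropped pairwise."""
    corr = spearman if method == "spearman" else pearson
    rows = []
    for name, column in CLINICAL_VARIABLES.items():
        cov = pd.to_numeric(clinical[column], errors="coerce")
        mask = cov.notna() & pd.Series(values).notna()
        if mask.sum() < 3:
            raise InsufficientDataError(f"fewer than 3 complete pairs for {name}")
        rho, p = corr(np.asarray(values)[mask], cov[mask])
        rows.append({"variable": name, "n": int(mask.sum()), "rho": rho, "p": p})
    return pd.DataFrame(rows)


def _subgroups(merged: pd.DataFrame) -> dict[str, tuple[pd.DataFrame, pd.DataFrame, str, str]]:
    """The registry's (x, y) subgroup pairs keyed by comparison id a..h."""
    con = merged[merged["group"] == "control"]
    pat = merged[merged["group"] == "patient"]
    tle = pat[pat["lobe"] == "temporal"]
    etle = pat[pat["lobe"] == "extratemporal"]
    tle_hs = tle[tle["lesional"] == "yes"]
    tle_nonles = tle[tle["lesional"] == "no"]
    nonles = pat[pat["lesional"] == "no"]
    right_tle = tle[tle["side"] == "R"]
    left_tle = tle[tle["side"] == "L"]
    ilae = pd.to_numeric(pat["ilae"], errors="coerce")
    good = pat[ilae <= 2]
    poor = pat[ilae >= 3]
    return {
        "a": (pat, con, "patients", "controls"),
        "b": (tle, con, "TLE", "controls"),
        "c": (etle, con, "ETLE", "controls"),
        "d": (tle_hs, con, "TLE-HS", "controls"),
        "e": (tle_nonles, con, "non-lesional TLE", "controls"),
        "f": (nonles, con, "non-lesional TLE&ETLE", "controls"),
        "g": (right_tle, left_tle, "right TLE", "left TLE"),
        "h": (good, poor, "ILAE 1-2", "ILAE 3-5"),
    }


def _compare(x: np.ndarray, y: np.ndarray, m: int) -> dict:
    u, p = mann_whitney_u(x, y)
    d, label = cohens_d(x, y)
    return {
        "n1": int(x.size), "n2": int(y.size), "U": u,
        "p_raw": p, "p_bonferroni": bonferroni(p, m),
        "cohen_d": d, "d_label": label,
    }


def run_comparison_registry(
    reports: pd.DataFrame, metadata: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Run the whole statistical battery on a cohort.

    ``reports`` carries one row per subject with ``subject_id``, ``ge_whole``
    and optionally ``ge_<rsn>`` columns; ``metadata`` is the cohort table.
    Returns (comparisons, diagnostics, correlations) as tidy frames. The
    whole-brain registry runs comparisons a-h with Bonferroni m=8; the RSN
    registry runs a-g per network with m=7 over networks. Comparisons whose
    subgroups are too small are skipped with a warning, never silently.
    """
    merged = reports.merge(metadata, on="subject_id", validate="one_to_one")
    groups = _subgroups(merged)
    rsn_cols = [f"ge_{r}" for r in RSN_LABELS if f"ge_{r}" in merged.columns]

    rows = []
    for cid, (gx, gy, name_x, name_y) in groups.items():
        targets = [("whole", "ge_whole", WHOLE_BRAIN_M)]
        if cid != "h":
            targets += [(col[3:], col, RSN_M) for col in rsn_cols]
        for network, col, m in targets:
            if len(gx) < 2 or len(gy) < 2:
                warnings.warn(
                    f"comparison {cid} ({name_x} vs {name_y}) skipped: "
                    f"subgroup sizes {len(gx)}/{len(gy)}",
                    stacklevel=2,
                )
                break
            rec = _compare(np.asarray(gx[col], dtype=float),
                           np.asarray(gy[col], dtype=float), m)
            rows.append({"comparison_id": cid, "network": network,
                         "group1": name_x, "group2": name_y, **rec})
    comparisons = pd.DataFrame(rows)

    diag_rows = []
    con_vals = np.asarray(groups["a"][1]["ge_whole"], dtype=float)
    for label, cid in (("patients", "a"), ("TLE", "b"), ("ETLE", "c")):
        gx = groups[cid][0]
        if len(gx) == 0:
            warnings.warn(f"diagnostics for {label} skipped: empty subgroup", stacklevel=2)
            continue
        rep = diagnostic_metrics(np.asarray(gx["ge_whole"], dtype=float), con_vals)
        diag_rows.append({"group": label, **rep.__dict__})
    diagnostics = pd.DataFrame(diag_rows)

    pat = groups["a"][0]
    correlations = clinical_correlations(
        pat["ge_whole"].reset_index(drop=True),
        pat[["onset_age", "duration", "ilae"]].reset_index(drop=True),
    )
    return comparisons, diagnostics, correlations
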