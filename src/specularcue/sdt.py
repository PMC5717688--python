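"""Signal-detection and group-level statistics.

Sensitivity and bias for the two-alternative classification are measured
with the equal-variance Gaussian model.  Illuminant-change trials are the
signal class and an "illuminant change" response is a yes:

    d'      = z(H) - z(F)
    ln beta = (z(F)^2 - z(H)^2) / 2

so d' = 0 is chance, and ln beta > 0 indicates a tendency toward
"reflectance change" responses.  Perfect hit or false-alarm proportions are
corrected by the 1/(2N) rule (0 -> 1/(2N), 1 -> 1 - 1/(2N), N = per-class
trial count), which bounds the measurable d' at 2 z(1 - 1/(2N)) — about
4.90 for the canonical 70-per-class cell.  Confidence intervals come from a
seeded nonparametric bootstrap over trial resampling; group-level effects
from a classical three-way repeated-measures ANOVA (surface type x motion
condition x specularity) on complete-case observers, without sphericity
correction.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.anova import AnovaRM

__all__ = [
    "SDTResult",
    "dprime_lnbeta",
    "max_measurable_dprime",
    "dprime_ci",
    "dprime_table",
    "normalize_relative",
    "rm_anova",
    "read_responses_csv",
]

_CELL_FACTORS = ["observer", "object_type", "motion_condition", "specularity_level"]


@dataclass(frozen=True)
class SDTResult:
    """Per-cell sensitivity and bias with trial counts and optional CI."""

    dprime: float
    ln_beta: float
    n_signal: int
    n_noise: int
    hits: int
    false_alarms: int
    ci_low: float = np.nan
    ci_high: float = np.nan


def _corrected_rate(count: int, n: int) -> float:
    rate = count / n
    eps = 1.0 / (2 * n)
    return min(max(rate, eps), 1.0 - eps)


def dprime_lnbeta(hits: int, false_alarms: int, n_signal: int, n_noise: int) -> SDTResult:
    """d' and ln(beta) from counts, with the 1/(2N) extreme-rate correction.

    Signal = illuminant-change trials; ``hits`` are "illuminant" responses
    on signal trials and ``false_alarms`` are "illuminant" responses on
    reflectance (noise) trials.
    """
    if n_signal < 1 or n_noise < 1:
        raise ValueError("both trial classes must be non-empty")
    if not (0 <= hits <= n_signal and 0 <= false_alarms <= n_noise):
        raise ValueError("counts outside [0, n]")
    zH = norm.ppf(_corrected_rate(hits, n_signal))
    zF = norm.ppf(_corrected_rate(false_alarms, n_noise))
    return SDTResult(
        dprime=float(zH - zF),
        ln_beta=float((zF**2 - zH**2) / 2.0),
        n_signal=n_signal,
        n_noise=n_noise,
        hits=hits,
        false_alarms=false_alarms,
    )


def max_measurable_dprime(n_per_class: int) -> float:
    """Ceiling on measurable d' under the 1/(2N) correction: 2 z(1 - 1/(2N)).

    A 140-trial cell (70 per class) caps at about 4.90."""
    if n_per_class < 1:
        raise ValueError("need at least one trial per class")
    return float(2.0 * norm.ppf(1.0 - 1.0 / (2 * n_per_class)))


def dprime_ci(result: SDTResult, level: float = 0.95, n_boot: int = 1999,
              seed: int = 0) -> tuple[float, float]:
    """Nonparametric bootstrap CI on d' by resampling the cell's trials.

    Trials are resampled with replacement within each truth class and the
    interval is bias-corrected and accelerated (BCa), which keeps coverage
    at the nominal level despite the discreteness of 70-trial classes and
    the skew of d' near its measurable ceiling.  Reproducible given seed.
    """
    from scipy.stats import bootstrap

    sig = np.zeros(result.n_signal)
    sig[:result.hits] = 1.0
    noi = np.zeros(result.n_noise)
    noi[:result.false_alarms] = 1.0

    def stat(s, n, axis=-1):
        ns, nn = s.shape[axis], n.shape[axis]
        H = np.clip(s.mean(axis=axis), 1 / (2 * ns), 1 - 1 / (2 * ns))
        F = np.clip(n.mean(axis=axis), 1 / (2 * nn), 1 - 1 / (2 * nn))
        return norm.ppf(H) - norm.ppf(F)

    import warnings

    with warnings.catch_warnings():
        # degenerate cells (all hits / no false alarms) are handled below
        warnings.simplefilter("ignore")
        res = bootstrap((sig, noi), stat, n_resamples=n_boot, method="BCa",
                        confidence_level=level, vectorized=True,
                        random_state=np.random.default_rng(seed))
    lo, hi = res.confidence_interval
    # degenerate cells (all-same responses) can yield one-sided collapse
    if not np.isfinite(lo):
        lo = stat(sig, noi) - (hi - stat(sig, noi) if np.isfinite(hi) else 1.0)
    if not np.isfinite(hi):
        hi = max_measurable_dprime(min(result.n_signal, result.n_noise))
    return float(lo), float(hi)


def with_ci(result: SDTResult, **kwargs) -> SDTResult:
    low, high = dprime_ci(result, **kwargs)
    return SDTResult(**{**result.__dict__, "ci_low": low, "ci_high": high})


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def dprime_table(responses: pd.DataFrame, ci: bool = False, n_boot: int = 2000,
                 seed: int = 0) -> pd.DataFrame:
    """Per-cell d' and ln(beta) from a long-format response table.

    Cells are (observer, object_type, motion_condition, specularity_level);
    each must contain at least one trial of each truth class.
    """
    rows = []
    for keys, cell in responses.groupby(_CELL_FACTORS, sort=True):
        sig = cell[cell["truth"] == "illuminant"]
        noi = cell[cell["truth"] == "reflectance"]
        if len(sig) == 0 or len(noi) == 0:
            raise ValueError(f"cell {keys} lacks one of the truth classes")
        res = dprime_lnbeta(
            int((sig["response"] == "illuminant").sum()),
            int((noi["response"] == "illuminant").sum()),
            len(sig), len(noi),
        )
        if ci:
            res = with_ci(res, n_boot=n_boot, seed=seed)
        rows.append(dict(zip(_CELL_FACTORS, keys)) | {
            "dprime": res.dprime, "ln_beta": res.ln_beta,
            "n_signal": res.n_signal, "n_noise": res.n_noise,
            "ci_low": res.ci_low, "ci_high": res.ci_high,
        })
    return pd.DataFrame(rows)


def normalize_relative(dtable: pd.DataFrame,
                       reference_condition: str = "NoMotion",
                       reference_object: str = "marbled",
                       per_level: bool = False) -> pd.DataFrame:
    """Normalize each observer's d' to their static-marbled performance.

    Default: division by a per-observer scalar, the mean static-marbled d'
    over the four nonzero specularity levels (per-level division is
    unstable where d' is near zero).  With ``per_level=True`` each level is
    divided by the observer's static-marbled d' at that same level, so the
    reference condition plots at exactly 1.  Observers lacking the
    reference cells are dropped with a warning column-free contract: they
    simply do not appear in the output.
    """
    out = []
    for obs, sub in dtable.groupby("observer"):
        ref = sub[(sub["motion_condition"] == reference_condition)
                  & (sub["object_type"] == reference_object)]
        if ref.empty:
            import warnings
            warnings.warn(f"observer {obs!r} lacks the reference condition; excluded")
            continue
        sub = sub.copy()
        if per_level:
            ref_by_level = ref.set_index("specularity_level")["dprime"]
            # zero reference cells (chance-level performance) yield NaN,
            # the documented instability of per-level division
            sub["dprime_rel"] = [
                r.dprime / ref_by_level[r.specularity_level]
                if ref_by_level[r.specularity_level] != 0 else np.nan
                for r in sub.itertuples()
            ]
        else:
            scalar = ref[ref["specularity_level"] > 0]["dprime"].mean()
            sub["dprime_rel"] = sub["dprime"] / scalar
        out.append(sub)
    if not out:
        raise ValueError("no observer has the reference condition")
    return pd.concat(out, ignore_index=True)


def rm_anova(dtable: pd.DataFrame) -> pd.DataFrame:
    """Three-way repeated-measures ANOVA on per-cell d'.

    Factors: object_type (surface), motion_condition and specularity_level,
    all within-subject; observers with incomplete cells are excluded
    (complete-case analysis).  Returns the statsmodels ANOVA table with
    F values and degrees of freedom for all main effects and interactions.
    """
    full_cells = (dtable.groupby("observer")[_CELL_FACTORS[1:]]
                  .apply(lambda g: len(g.drop_duplicates())))
    n_cells = full_cells.max()
    complete = full_cells[full_cells == n_cells].index
    sub = dtable[dtable["observer"].isin(complete)].copy()
    if sub.empty or len(complete) < 2:
        raise ValueError("need at least two complete-case observers")
    counts = sub.groupby("observer").size()
    if counts.nunique() != 1:
        raise ValueError("unbalanced table after complete-case filtering")
    res = AnovaRM(
        sub, depvar="dprime", subject="observer",
        within=["object_type", "motion_condition", "specularity_level"],
    ).fit()
    return res.anova_table


# ---------------------------------------------------------------------------
# Response-table I/O
# ---------------------------------------------------------------------------

_CANONICAL = ["observer", "object_type", "motion_condition",
              "specularity_level", "truth", "response"]

# Tolerant header synonyms for externally produced response tables.
_SYNONYMS = {
    "observer": {"observer", "obs", "subject", "participant", "observer_id"},
    "object_type": {"object_type", "object", "surface", "surface_type", "stimulus"},
    "motion_condition": {"motion_condition", "motion", "condition", "rotation"},
    "specularity_level": {"specularity_level", "spec_level", "level"},
    "specularity": {"specularity", "spec", "s"},
    "truth": {"truth", "change", "change_type", "stimulus_change", "correct_answer"},
    "response": {"response", "resp", "answer", "judgement", "judgment"},
}


def _canon_label(x: str) -> str:
    x = str(x).strip().lower()
    if "illum" in x or x in {"i", "light", "lighting"}:
        return "illuminant"
    if "refl" in x or "surf" in x or x in {"r", "surface"}:
        return "reflectance"
    raise ValueError(f"cannot interpret class label {x!r}")


def read_responses_csv(path) -> pd.DataFrame:
    """Read a trial-level response table, canonical or dialect.

    Accepts comma or semicolon separation and common column-name synonyms;
    class labels containing "illum"/"refl" (any case) are canonicalized.
    A ``specularity`` value column is converted to level indices when the
    level column is absent.  Raises with the offending columns when the
    schema cannot be interpreted.
    """
    text = Path(path).read_text()
    first = text.splitlines()[0]
    sep = ";" if first.count(";") > first.count(",") else ","
    df = pd.read_csv(io.StringIO(text), sep=sep, skipinitialspace=True)
    df.columns = [str(c).strip().lower() for c in df.columns]
    mapping = {}
    for canon, alts in _SYNONYMS.items():
        for c in df.columns:
            if c in alts:
                mapping[canon] = c
                break
    missing = [c for c in _CANONICAL if c not in mapping]
    if "specularity_level" in missing and "specularity" in mapping:
        vals = np.sort(df[mapping["specularity"]].unique())
        lut = {v: i for i, v in enumerate(vals)}
        df["__level"] = df[mapping["specularity"]].map(lut)
        mapping["specularity_level"] = "__level"
        missing = [c for c in _CANONICAL if c not in mapping]
    if missing:
        raise ValueError(f"response table missing columns: {missing}; "
                         f"found {list(df.columns)}")
    out = pd.DataFrame({c: df[mapping[c]] for c in _CANONICAL})
    out["truth"] = out["truth"].map(_canon_label)
    out["response"] = out["response"].map(_canon_label)
    out["specularity_level"] = out["specularity_level"].astype(int)
    return out
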