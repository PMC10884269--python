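"""Statistical pipeline for sessions, questionnaires and coding tables.

Covers the full analysis stack of the experiment: per-condition
intelligibility tables, a 2 x 3 x 4 fully within-subjects ANOVA with
Mauchly's sphericity test and Greenhouse-Geisser correction, BIC-based
Bayes factors for each effect (evidence *for the null* is the quantity of
interest when comparing the two interfaces), paired t-tests on
data-collection durations, NARS subscale scoring against neutral means,
Shrout-Fleiss ICC(2,k) inter-coder reliability, and per-behaviour
within-coder comparisons.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .listener import BEHAVIOURS, NARS_ITEMS, NARS_NEUTRAL_TOTALS, CodingRecord
from .masker import TMR_SET_DB
from .protocol import SessionResult, TRIALS_PER_CONDITION
from .voice import VOICE_CONDITIONS

__all__ = [
    "intelligibility_table",
    "baseline_table",
    "rmanova3",
    "bayes_rmanova",
    "evidence_category",
    "duration_tests",
    "nars_score",
    "icc_2k",
    "behaviour_compare",
    "AnalysisReport",
    "full_report",
]

_FACTORS = ("interface", "tmr_db", "voice")
_LEVELS = {
    "interface": ("computer", "robot"),
    "tmr_db": TMR_SET_DB,
    "voice": tuple(vc.name for vc in VOICE_CONDITIONS),
}


def _sessions_flat(
    sessions: Iterable[SessionResult | tuple[SessionResult, SessionResult]],
) -> list[SessionResult]:
    flat: list[SessionResult] = []
    for s in sessions:
        if isinstance(s, SessionResult):
            flat.append(s)
        else:
            flat.extend(s)
    return flat


def intelligibility_table(
    sessions: Iterable[SessionResult | tuple[SessionResult, SessionResult]],
) -> pd.DataFrame:
    """Percent-correct per participant x interface x TMR x voice cell.

    Baseline trials are excluded (they are a paradigm check, not part of the
    2 x 3 x 4 design).  Participants with incomplete cell designs are
    dropped with a warning.
    """
    rows = []
    for sess in _sessions_flat(sessions):
        for tr in sess.trials:
            if tr.condition.baseline:
                continue
            rows.append(
                {
                    "participant": sess.participant_id,
                    "interface": sess.interface,
                    "tmr_db": tr.condition.tmr_db,
                    "voice": tr.condition.voice,
                    "correct": float(tr.correct),
                }
            )
    if not rows:
        raise ValueError("no experimental trials found")
    df = pd.DataFrame(rows)
    table = (
        df.groupby(["participant", "interface", "tmr_db", "voice"], sort=True)
        ["correct"].mean().mul(100.0).rename("percent").reset_index()
    )
    n_cells = len(TMR_SET_DB) * len(VOICE_CONDITIONS)
    counts = table.groupby(["participant", "interface"]).size()
    bad = counts[counts != n_cells].index.get_level_values(0).unique()
    if len(bad):
        warnings.warn(
            f"dropping participants with incomplete designs: {sorted(bad)}",
            stacklevel=2,
        )
        table = table[~table["participant"].isin(bad)]
    return table.reset_index(drop=True)


def baseline_table(
    sessions: Iterable[SessionResult | tuple[SessionResult, SessionResult]],
) -> pd.DataFrame:
    """Baseline (no-masker) percent correct per participant x interface."""
    rows = []
    for sess in _sessions_flat(sessions):
        vals = [float(t.correct) for t in sess.trials if t.condition.baseline]
        if vals:
            rows.append(
                {
                    "participant": sess.participant_id,
                    "interface": sess.interface,
                    "percent": 100.0 * float(np.mean(vals)),
                }
            )
    return pd.DataFrame(rows)


def _design_array(table: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Reshape the tidy table to y[subject, interface, tmr, voice]."""
    participants = sorted(table["participant"].unique())
    sizes = (len(participants),) + tuple(len(_LEVELS[f]) for f in _FACTORS)
    idx = pd.MultiIndex.from_product(
        [participants, *(_LEVELS[f] for f in _FACTORS)],
        names=["participant", *_FACTORS],
    )
    series = table.set_index(["participant", *_FACTORS])["percent"]
    if series.index.duplicated().any():
        raise ValueError("duplicate design cells in the table")
    y = series.reindex(idx).to_numpy().reshape(sizes)
    if np.isnan(y).any():
        raise ValueError("incomplete within-subjects design")
    return y, participants


def _effect_term(y: np.ndarray, dims: tuple[int, ...]) -> np.ndarray:
    """Centred effect term: centre along ``dims``, average along the rest."""
    out = y
    for d in range(y.ndim):
        if d in dims:
            out = out - out.mean(axis=d, keepdims=True)
        else:
            out = out.mean(axis=d, keepdims=True)
    return out


def _ss(y: np.ndarray, dims: tuple[int, ...]) -> float:
    term = _effect_term(y, dims)
    mult = np.prod([y.shape[d] for d in range(y.ndim) if d not in dims])
    return float(mult * np.sum(np.square(term)))


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k matrix with orthonormal rows, each orthogonal to the mean."""
    h = linalg.helmert(k)
    return h


def _effect_contrast(sizes: Sequence[int]) -> np.ndarray:
    c = np.ones((1, 1))
    for k in sizes:
        c = np.kron(c, _orthonormal_contrasts(k))
    return c


def _sphericity(y: np.ndarray, dims: tuple[int, ...]) -> dict:
    """Mauchly's test and GG epsilon for one within effect.

    ``y`` is subject x factor-level array; the effect's cell matrix is the
    subject-by-cells collapse over the uninvolved factors.
    """
    n = y.shape[0]
    sizes = [y.shape[d] for d in dims]
    df = int(np.prod([k - 1 for k in sizes]))
    collapse_dims = [d for d in range(1, y.ndim) if d not in dims]
    m = y.mean(axis=tuple(collapse_dims), keepdims=False) if collapse_dims else y
    m = m.reshape(n, -1)
    contrast = _effect_contrast(sizes)
    z = m @ contrast.T  # n x df
    s = np.cov(z, rowvar=False)
    s = np.atleast_2d(s)
    tr = np.trace(s)
    if tr <= 0:
        return {"mauchly_w": np.nan, "mauchly_p": np.nan, "gg_eps": 1.0}
    eps = float(tr**2 / (df * np.sum(s * s.T)))
    eps = min(1.0, max(eps, 1.0 / df))
    eigs = np.linalg.eigvalsh(s)
    eigs = np.clip(eigs, 1e-300, None)
    w = float(np.exp(np.sum(np.log(eigs))) / (tr / df) ** df)
    d_chi = df * (df + 1) // 2 - 1
    if d_chi <= 0 or n - 1 <= df:
        return {"mauchly_w": w, "mauchly_p": np.nan, "gg_eps": eps}
    f_corr = 1.0 - (2 * df**2 + df + 2) / (6.0 * df * (n - 1))
    chi2 = -(n - 1) * f_corr * np.log(max(w, 1e-300))
    p = float(stats.chi2.sf(chi2, d_chi))
    return {"mauchly_w": w, "mauchly_p": p, "gg_eps": eps}


def rmanova3(table: pd.DataFrame, sphericity_alpha: float = 0.05) -> pd.DataFrame:
    """Three-way fully within-subjects ANOVA on the intelligibility table.

    Returns one row per effect (3 main effects, 3 two-way interactions, the
    three-way interaction) with F, degrees of freedom, p, partial eta
    squared, and -- for effects with more than 1 numerator df -- Mauchly's
    test and the Greenhouse-Geisser corrected df and p.  ``p_report``
    carries the GG-corrected p whenever Mauchly's test rejects sphericity at
    ``sphericity_alpha``, and the uncorrected p otherwise.
    """
    y, participants = _design_array(table)
    n = y.shape[0]
    if n < 3:
        raise ValueError("need at least 3 participants for the RM-ANOVA")
    rows = []
    factor_dims = {"interface": 1, "tmr_db": 2, "voice": 3}
    for r in range(1, 4):
        for combo in itertools.combinations(_FACTORS, r):
            dims = tuple(factor_dims[f] for f in combo)
            ss_eff = _ss(y, dims)
            ss_err = _ss(y, (0, *dims))
            df_eff = int(np.prod([y.shape[d] - 1 for d in dims]))
            df_err = (n - 1) * df_eff
            ms_eff = ss_eff / df_eff
            ms_err = ss_err / df_err
            f_val = ms_eff / ms_err if ms_err > 0 else (0.0 if ms_eff == 0 else np.inf)
            p = float(stats.f.sf(f_val, df_eff, df_err)) if np.isfinite(f_val) else 0.0
            pes = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
            row = {
                "effect": " * ".join(combo),
                "ss": ss_eff,
                "ss_error": ss_err,
                "df1": df_eff,
                "df2": df_err,
                "F": f_val,
                "p": p,
                "partial_eta_sq": pes,
                "mauchly_w": np.nan,
                "mauchly_p": np.nan,
                "gg_eps": np.nan,
                "df1_gg": np.nan,
                "df2_gg": np.nan,
                "p_gg": np.nan,
                "sphericity_violated": False,
            }
            if df_eff > 1:
                sph = _sphericity(y, dims)
                eps = sph["gg_eps"]
                row.update(
                    mauchly_w=sph["mauchly_w"],
                    mauchly_p=sph["mauchly_p"],
                    gg_eps=eps,
                    df1_gg=df_eff * eps,
                    df2_gg=df_err * eps,
                    p_gg=float(stats.f.sf(f_val, df_eff * eps, df_err * eps))
                    if np.isfinite(f_val)
                    else 0.0,
                    sphericity_violated=bool(
                        np.isfinite(sph["mauchly_p"])
                        and sph["mauchly_p"] < sphericity_alpha
                    ),
                )
            row["p_report"] = row["p_gg"] if row["sphericity_violated"] else row["p"]
            rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["n_participants"] = n
    out.attrs["ss_total"] = float(np.sum((y - y.mean()) ** 2))
    return out


def bayes_rmanova(table: pd.DataFrame) -> pd.DataFrame:
    """BF10 per effect via the BIC approximation, on matched models.

    For each effect the comparison is made within its own repeated-measures
    error stratum: the subject-by-cells collapse of the design is modelled
    with and without the effect (subject terms in both), and
    ``BF10 = exp((BIC_without - BIC_with) / 2)``.  BF10 < 1 is evidence for
    the null; the interface effects are the ones expected to fall there
    when the two setups are functionally equivalent.
    """
    y, _ = _design_array(table)
    n = y.shape[0]
    rows = []
    factor_dims = {"interface": 1, "tmr_db": 2, "voice": 3}
    for r in range(1, 4):
        for combo in itertools.combinations(_FACTORS, r):
            dims = tuple(factor_dims[f] for f in combo)
            # collapse over uninvolved factors -> subject x cells stratum
            other = tuple(d for d in (1, 2, 3) if d not in dims)
            mc = y.mean(axis=other) if other else y  # (n, *effect sizes)
            m2 = mc.reshape(n, -1)
            n_obs = m2.size
            grand = m2.mean()
            subj = m2.mean(axis=1, keepdims=True)
            cell = m2.mean(axis=0, keepdims=True)
            # full model: subject + every cell term; reduced: full minus the
            # target effect's own (highest-order) term
            sse_full = float(np.sum((m2 - subj - cell + grand) ** 2))
            eff = _effect_term(mc, tuple(range(1, mc.ndim)))
            ss_eff = float(n * np.sum(eff**2))
            sse_red = sse_full + ss_eff
            df_eff = int(np.prod([y.shape[d] - 1 for d in dims]))
            if sse_full <= 0:
                bf10 = np.inf if sse_red > 0 else 1.0
                flagged = True
            else:
                delta_bic = n_obs * np.log(sse_red / sse_full) - df_eff * np.log(n_obs)
                bf10 = float(np.exp(delta_bic / 2.0))
                flagged = False
            cat, direction = evidence_category(bf10) if bf10 > 0 else ("", "")
            rows.append(
                {
                    "effect": " * ".join(combo),
                    "bf10": bf10,
                    "evidence": cat,
                    "direction": direction,
                    "degenerate": flagged,
                }
            )
    return pd.DataFrame(rows)


def evidence_category(bf10: float) -> tuple[str, str]:
    """Evidence label and direction for a Bayes factor.

    Categories follow the conventional thresholds: anecdotal (1/3-3),
    medium (1/10-1/3 or 3-10), strong (0.03-0.1 or 10-30) and beyond-strong
    outside those; direction is "null" for BF10 < 1 and "alternative" for
    BF10 > 1 (BF10 of exactly 1 is the anecdotal boundary, no direction).
    """
    if not (bf10 > 0):
        raise ValueError(f"Bayes factor must be positive, got {bf10!r}")
    if bf10 == 1.0:
        return "anecdotal", "none"
    direction = "null" if bf10 < 1.0 else "alternative"
    b = bf10 if bf10 > 1.0 else 1.0 / bf10
    if b < 3.0:
        cat = "anecdotal"
    elif b < 10.0:
        cat = "medium"
    elif b < 30.0:
        cat = "strong"
    else:
        cat = "beyond-strong"
    return cat, direction


def duration_tests(
    pairs: Sequence[tuple[SessionResult, SessionResult]],
    exclude: Sequence[str] = (),
) -> dict:
    """Paired t-test on per-participant data-collection durations.

    ``pairs`` holds (computer, robot) sessions per participant; ``exclude``
    names participants to drop (outlier handling), reported alongside.
    """
    if not pairs:
        raise ValueError("no paired sessions")
    rows = []
    for comp, robot in pairs:
        if comp.participant_id != robot.participant_id:
            raise ValueError("unpaired sessions: participant ids differ")
        rows.append(
            {
                "participant": comp.participant_id,
                "computer_min": comp.data_collection_duration_min,
                "robot_min": robot.data_collection_duration_min,
            }
        )
    df = pd.DataFrame(rows)
    kept = df[~df["participant"].isin(exclude)]
    diffs = kept["robot_min"] - kept["computer_min"]
    if diffs.std(ddof=1) == 0:
        t, p = (0.0, 1.0) if diffs.mean() == 0 else (np.inf, 0.0)
    else:
        t, p = stats.ttest_rel(kept["robot_min"], kept["computer_min"])
    return {
        "durations": df,
        "excluded": list(exclude),
        "n": len(kept),
        "mean_computer_min": float(kept["computer_min"].mean()),
        "sd_computer_min": float(kept["computer_min"].std(ddof=1)),
        "mean_robot_min": float(kept["robot_min"].mean()),
        "sd_robot_min": float(kept["robot_min"].std(ddof=1)),
        "mean_diff_min": float(diffs.mean()),
        "t": float(t),
        "df": len(kept) - 1,
        "p": float(p),
    }


def nars_score(questionnaires: np.ndarray | pd.DataFrame) -> dict:
    """Subscale totals and one-sample t-tests against the neutral means.

    Reverse-coded items contribute ``6 - rating``; the neutral expectation
    (every answer 3) is 18/15/9 for S1/S2/S3.  Zero-variance subscales are
    flagged instead of producing a t statistic.
    """
    arr = np.asarray(questionnaires, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != len(NARS_ITEMS):
        raise ValueError(f"expected an (n, {len(NARS_ITEMS)}) response array")
    if np.any((arr < 1) | (arr > 5)) or np.any(arr != np.round(arr)):
        raise ValueError("ratings must be integers in 1..5")
    out: dict[str, dict] = {}
    for sub in ("S1", "S2", "S3"):
        idx = [i for i, (s, _) in enumerate(NARS_ITEMS) if s == sub]
        contribs = np.array(
            [
                (6 - arr[:, i]) if NARS_ITEMS[i][1] else arr[:, i]
                for i in idx
            ]
        ).T
        totals = contribs.sum(axis=1)
        neutral = NARS_NEUTRAL_TOTALS[sub]
        n = len(totals)
        mean = float(np.mean(totals))
        sd = float(np.std(totals, ddof=1)) if n > 1 else 0.0
        res: dict = {
            "totals": totals,
            "mean": mean,
            "sd": sd,
            "neutral": neutral,
            "n": n,
        }
        if sd == 0 or n < 2:
            res.update(t=np.nan, p=np.nan, ci95=(mean, mean), zero_variance=True)
        else:
            t, p = stats.ttest_1samp(totals, neutral)
            half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
            res.update(
                t=float(t), p=float(p), ci95=(mean - half, mean + half),
                zero_variance=False,
            )
        out[sub] = res
    return out


def icc_2k(counts: np.ndarray) -> float:
    """Shrout-Fleiss ICC(2,k): two-way random, absolute agreement, average.

    ``counts`` is segments x coders.  Computed from the two-way ANOVA mean
    squares; returns NaN (flagged) when the table has no variance at all.
    """
    m = np.asarray(counts, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need at least 2 segments and 2 coders")
    n, k = m.shape
    grand = m.mean()
    if np.allclose(m, grand):
        warnings.warn("zero total variance: ICC undefined", stacklevel=2)
        return float("nan")
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((m - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (msc - mse) / n))


def behaviour_compare(records: Sequence[CodingRecord]) -> pd.DataFrame:
    """Per-behaviour, per-coder interface comparison (paired t over segments).

    Pairs each coder's computer and robot counts by participant segment and
    reports totals and the Student t-test per behaviour.
    """
    rows = [
        {
            "coder": r.coder_id,
            "interface": r.interface,
            "participant": r.segment_id.split("_")[0],
            **{b: r.counts.get(b, 0) for b in BEHAVIOURS},
        }
        for r in records
    ]
    df = pd.DataFrame(rows)
    if df["interface"].nunique() < 2:
        raise ValueError("need records for both interfaces")
    out = []
    for coder, dc in df.groupby("coder"):
        wide = dc.pivot_table(
            index="participant", columns="interface", values=list(BEHAVIOURS)
        )
        for b in BEHAVIOURS:
            comp = wide[(b, "computer")].dropna()
            rob = wide[(b, "robot")].dropna()
            common = comp.index.intersection(rob.index)
            c, r = comp[common].to_numpy(), rob[common].to_numpy()
            if np.std(r - c, ddof=1) == 0:
                t, p = (0.0, 1.0) if np.mean(r - c) == 0 else (np.inf, 0.0)
            else:
                t, p = stats.ttest_rel(r, c)
            out.append(
                {
                    "coder": coder,
                    "behaviour": b,
                    "total_computer": int(c.sum()),
                    "total_robot": int(r.sum()),
                    "t": float(t),
                    "df": len(common) - 1,
                    "p": float(p),
                }
            )
    return pd.DataFrame(out)


@dataclass
class AnalysisReport:
    """Bundle of every table the pipeline produces."""

    intelligibility: pd.DataFrame
    baseline: pd.DataFrame
    anova: pd.DataFrame
    bayes: pd.DataFrame
    durations: dict
    nars: dict | None = None
    icc: dict | None = None
    behaviours: pd.DataFrame | None = None


def full_report(
    pairs: Sequence[tuple[SessionResult, SessionResult]],
    nars_responses: np.ndarray | None = None,
    coding_records: Sequence[CodingRecord] | None = None,
    duration_exclude: Sequence[str] = (),
) -> AnalysisReport:
    """Run the complete statistical pipeline on a cohort."""
    table = intelligibility_table(pairs)
    if table["participant"].nunique() < 3:
        warnings.warn(
            "fewer than 3 participants: ANOVA and Bayes tables are empty",
            stacklevel=2,
        )
        anova, bayes = pd.DataFrame(), pd.DataFrame()
    else:
        anova, bayes = rmanova3(table), bayes_rmanova(table)
    report = AnalysisReport(
        intelligibility=table,
        baseline=baseline_table(pairs),
        anova=anova,
        bayes=bayes,
        durations=duration_tests(pairs, exclude=duration_exclude),
    )
    if nars_responses is not None:
        report.nars = nars_score(nars_responses)
    if coding_records is not None:
        df = pd.DataFrame(
            [
                {"coder": r.coder_id, "segment": r.segment_id, **r.counts}
                for r in coding_records
            ]
        )
        icc = {}
        for b in BEHAVIOURS:
            wide = df.pivot_table(index="segment", columns="coder", values=b)
            icc[b] = icc_2k(wide.to_numpy())
        report.icc = icc
        report.behaviours = behaviour_compare(coding_records)
    return report
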