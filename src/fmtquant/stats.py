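"""Hierarchical statistics for image-derived indices.

The measurement design is nested: treatment groups are imaged as several
fields (images) per specimen, replicated across independent experiments.
Indices are positive and right-skewed, so the model is a Gamma generalized
linear mixed model with a square-root link:

    value ~ group + (1 | experiment) + (1 | experiment:specimen)

Images within a specimen share the specimen intercept; the Gamma residual
carries image-to-image variability. (An image-level intercept would be an
observation-level random effect, unidentifiable from the Gamma residual
with one index per image.) The optimizer is delegated to an established
mixed-model routine (glmmTMB via Rscript); this module owns model assembly,
the nesting structure, estimated marginal means on the response scale, and
treatment-vs-control contrasts with Benjamini-Hochberg adjustment.

When the random-effect structure is inestimable (single experiment and a
single specimen), the model falls back to a fixed-effects Gamma GLM
(statsmodels) with a logged warning and an explicit ``fallback`` flag.

Zero-valued indices (possible for PLA fields with zero puncta) violate the
Gamma support; by default they receive the smallest half-resolution offset
``0.5 / nuclei_count`` (logged, opt-out via ``zero_offset=False``) —
discarding them would bias the group means upward.
"""

from __future__ import annotations

import json
import logging
import subprocess
import tempfile
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .datatypes import MeasurementRecord

logger = logging.getLogger(__name__)

_REQUIRED = ("value", "group", "specimen", "image", "experiment")


class GLMMError(RuntimeError):
    """Raised on model-assembly or convergence failures (never silent)."""


@dataclass
class GLMMResult:
    """Fitted marginal means and contrasts of one analysis.

    ``emm``: one row per group — estimated marginal mean on the response
    scale with a 95% interval, plus the link-scale estimate and SE.
    ``contrasts``: one row per non-control group — link-scale estimate,
    response-scale ratio with interval, raw and BH-adjusted p-values.
    """

    emm: pd.DataFrame
    contrasts: pd.DataFrame
    converged: bool
    fallback: bool
    random_sd: dict = field(default_factory=dict)
    df: float = float("inf")
    model: str = ""
    n_zero_offset: int = 0


def adjust_fdr(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved.

    Adjusted p-values are ``p * m / rank`` with the running minimum taken
    from the largest rank down (monotonicity enforcement), capped at 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        frame = records.copy()
    else:
        frame = pd.DataFrame([r.__dict__ for r in records])
    missing = set(_REQUIRED) - set(frame.columns)
    if missing:
        raise ValueError(f"records missing fields: {sorted(missing)}")
    return frame


def _handle_zeros(frame: pd.DataFrame, zero_offset) -> tuple[pd.DataFrame, int]:
    """Apply the half-resolution offset to zero values; reject negatives."""
    bad = frame[frame["value"] < 0]
    if len(bad):
        raise ValueError(f"negative values are outside the Gamma support: {bad.index.tolist()}")
    zero = frame["value"] == 0
    if not zero.any():
        return frame, 0
    if zero_offset is False:
        raise ValueError(
            f"zero values at rows {frame.index[zero].tolist()} violate Gamma "
            "support (zero_offset=False)"
        )
    frame = frame.copy()
    if zero_offset is True or zero_offset is None:
        if "nuclei_count" not in frame.columns:
            raise ValueError(
                "zero values present but no nuclei_count column to derive the "
                "half-resolution offset; pass zero_offset=<float> explicitly"
            )
        offsets = 0.5 / frame.loc[zero, "nuclei_count"].astype(float)
    else:
        offsets = float(zero_offset)
    frame.loc[zero, "value"] = frame.loc[zero, "value"] + offsets
    logger.warning(
        "offset %d zero-valued indices by the half-resolution rule before "
        "Gamma modeling", int(zero.sum())
    )
    return frame, int(zero.sum())


# ---------------------------------------------------------------------------
# delegated mixed-model backend
# ---------------------------------------------------------------------------

def _r_script_path() -> Path:
    return Path(resources.files("fmtquant") / "_glmm_fit.R")


def _run_r_backend(
    frames: Sequence[pd.DataFrame], control: str, want_emmeans: bool = False
) -> list[dict]:
    stacked = pd.concat(
        [f.assign(dataset=str(i)) for i, f in enumerate(frames)], ignore_index=True
    )
    with tempfile.TemporaryDirectory() as tmp:
        data_path = Path(tmp) / "data.csv"
        out_path = Path(tmp) / "fits.json"
        stacked.to_csv(data_path, index=False)
        cmd = ["Rscript", "--vanilla", str(_r_script_path()), str(data_path),
               str(out_path), control]
        if want_emmeans:
            cmd.append("--emmeans")
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0 or not out_path.exists():
            raise GLMMError(
                f"mixed-model backend failed (exit {proc.returncode}):\n{proc.stderr[-2000:]}"
            )
        fits = json.loads(out_path.read_text())
    return [fits[str(i)] for i in range(len(frames))]


def _needs_fallback(frame: pd.DataFrame) -> bool:
    n_exp = frame["experiment"].nunique()
    n_spec = frame.groupby(["experiment", "specimen"]).ngroups
    return n_exp < 2 and n_spec < 2


def _fallback_glm(frame: pd.DataFrame, control: str, groups: list[str]) -> dict:
    """Fixed-effects Gamma GLM with sqrt link (no estimable random effects)."""
    import statsmodels.api as sm

    logger.warning(
        "random-effect variances inestimable (single experiment, single "
        "specimen); falling back to a fixed-effects Gamma GLM"
    )
    X = pd.get_dummies(
        pd.Categorical(frame["group"], categories=groups), drop_first=True, dtype=float
    )
    X.insert(0, "(Intercept)", 1.0)
    X.columns = ["(Intercept)"] + [f"group{g}" for g in groups[1:]]
    model = sm.GLM(
        frame["value"].to_numpy(), X.to_numpy(),
        family=sm.families.Gamma(link=sm.families.links.Power(0.5), check_link=False),
    )
    fit = model.fit()
    return {
        "coef_names": list(X.columns),
        "beta": list(np.asarray(fit.params, dtype=float)),
        "vcov": np.asarray(fit.cov_params(), dtype=float).tolist(),
        "converged": bool(fit.converged),
        "random_terms": [],
        "re_sd": {},
        "fallback": True,
    }


# ---------------------------------------------------------------------------
# EMM and contrast construction (owned here, backend-independent)
# ---------------------------------------------------------------------------

def _summarize_fit(
    fit: dict, groups: list[str], control: str, df: float = float("inf")
) -> GLMMResult:
    """EMMs and treatment-vs-control contrasts from coefficients + vcov.

    Inference is asymptotic Wald (normal reference, ``df = inf``) on the
    link scale, matching the estimated-marginal-means convention for GLMMs;
    the weak variance regularization in the backend keeps it calibrated in
    small designs. A finite ``df`` switches to a t reference.
    """
    if "error" in fit:
        raise GLMMError(f"mixed-model fit failed: {fit['error']}")
    beta = np.asarray(fit["beta"], dtype=float)
    vcov = np.asarray(fit["vcov"], dtype=float).reshape(len(beta), len(beta))
    names = list(fit["coef_names"])
    # link-scale EMM design: intercept row for control, intercept + own
    # coefficient for the others (treatment coding, group-only fixed effects)
    L = np.zeros((len(groups), len(beta)))
    L[:, names.index("(Intercept)")] = 1.0
    for i, g in enumerate(groups):
        if g == control:
            continue
        L[i, names.index(f"group{g}")] = 1.0
    eta = L @ beta
    if np.all(eta < 0):
        # global sign flip of the linear predictor is an exact likelihood
        # invariance of the sqrt link (with symmetric random effects);
        # canonicalize to the positive branch
        beta, eta = -beta, -eta
    if np.any(eta <= 0):
        raise GLMMError(
            "fit landed on a mixed-sign branch of the sqrt link "
            f"(link-scale means {eta.tolist()}); the model is not interpretable"
        )
    se = np.sqrt(np.einsum("ij,jk,ik->i", L, vcov, L))
    tcrit = float(sps.t.ppf(0.975, df))
    emm = pd.DataFrame(
        {
            "group": groups,
            "emm": eta**2,
            "lower": np.clip(eta - tcrit * se, 0, None) ** 2,
            "upper": (eta + tcrit * se) ** 2,
            "eta_link": eta,
            "se_link": se,
        }
    )
    rows = []
    i0 = groups.index(control)
    for i, g in enumerate(groups):
        if g == control:
            continue
        c = L[i] - L[i0]
        est = float(c @ beta)
        cse = float(np.sqrt(c @ vcov @ c))
        z = est / cse if cse > 0 else np.inf * np.sign(est or 1)
        p = float(2 * sps.t.sf(abs(z), df))
        ratio = float((eta[i] / eta[i0]) ** 2)
        # delta method on log ratio = 2(log eta_g - log eta_ctrl)
        var_log = 4 * (
            vcov_quad(L[i], vcov) / eta[i] ** 2
            + vcov_quad(L[i0], vcov) / eta[i0] ** 2
            - 2 * float(L[i] @ vcov @ L[i0]) / (eta[i] * eta[i0])
        )
        sd_log = np.sqrt(max(var_log, 0.0))
        rows.append(
            dict(
                group=g, estimate_link=est, se_link=cse,
                ratio=ratio,
                ratio_lower=float(ratio * np.exp(-tcrit * sd_log)),
                ratio_upper=float(ratio * np.exp(tcrit * sd_log)),
                p=p,
            )
        )
    contrasts = pd.DataFrame(
        rows, columns=["group", "estimate_link", "se_link", "ratio",
                       "ratio_lower", "ratio_upper", "p"]
    )
    contrasts["p_adj"] = adjust_fdr(contrasts["p"]) if len(contrasts) else []
    if not fit.get("converged", False):
        logger.warning("mixed-model fit did not fully converge; estimates reported with flag")
    return GLMMResult(
        emm=emm,
        contrasts=contrasts,
        converged=bool(fit.get("converged", False)),
        fallback=bool(fit.get("fallback", False)),
        random_sd=dict(fit.get("re_sd", {}) or {}),
        df=df,
        model="value ~ group"
        + "".join(f" + {t}" for t in fit.get("random_terms", [])),
    )


def vcov_quad(l: np.ndarray, V: np.ndarray) -> float:
    return float(l @ V @ l)


def fit_glmm_batch(
    datasets: Sequence[pd.DataFrame | Sequence[MeasurementRecord]],
    control: str,
    zero_offset=True,
) -> list[GLMMResult]:
    """Fit the Gamma GLMM to many measurement tables in one backend call.

    Simulation studies fit hundreds of replicate datasets; batching them
    into a single backend invocation amortizes its startup cost. Returns
    one :class:`GLMMResult` per dataset, in order.
    """
    frames, n_offsets = [], []
    for ds in datasets:
        frame = _as_frame(ds)
        if frame["group"].nunique() < 1:
            raise ValueError("dataset has no groups")
        frame, n_off = _handle_zeros(frame, zero_offset)
        frames.append(frame)
        n_offsets.append(n_off)
    group_lists = []
    for frame in frames:
        groups = sorted(frame["group"].unique())
        if control in groups:
            groups.remove(control)
            groups.insert(0, control)
        else:
            raise ValueError(f"control group {control!r} absent from data")
        group_lists.append(groups)
    results: list[GLMMResult | None] = [None] * len(frames)
    r_jobs = [i for i, f in enumerate(frames) if not _needs_fallback(f)]
    for i, frame in enumerate(frames):
        if i not in r_jobs:
            fit = _fallback_glm(frame, control, group_lists[i])
            results[i] = _summarize_fit(fit, group_lists[i], control)
    if r_jobs:
        fits = _run_r_backend([frames[i] for i in r_jobs], control)
        for i, fit in zip(r_jobs, fits):
            results[i] = _summarize_fit(fit, group_lists[i], control)
    for i, n_off in enumerate(n_offsets):
        results[i].n_zero_offset = n_off
    return results  # type: ignore[return-value]


def fit_glmm(
    records: pd.DataFrame | Sequence[MeasurementRecord],
    control: str,
    zero_offset=True,
) -> GLMMResult:
    """Fit the Gamma(sqrt-link) GLMM with nested random intercepts.

    ``records`` is a tidy table (or list of MeasurementRecords) with
    value/group/specimen/image/experiment; ``control`` names the reference
    group for the treatment-vs-control contrasts. See the module docstring
    for the model, the fallback rule and zero handling.
    """
    return fit_glmm_batch([records], control, zero_offset=zero_offset)[0]


def emmeans_crosscheck(
    records: pd.DataFrame | Sequence[MeasurementRecord], control: str
) -> dict:
    """Independent EMM/contrast computation via the R emmeans package.

    Used in tests to validate the Python-side EMM and contrast construction
    against an established implementation on the same fitted model.
    """
    frame = _as_frame(records)
    fit = _run_r_backend([frame], control, want_emmeans=True)[0]
    if "error" in fit or "emmeans" not in fit:
        raise GLMMError(f"emmeans cross-check failed: {fit.get('error', 'no emmeans output')}")
    return fit["emmeans"]
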