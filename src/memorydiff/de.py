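"""Differential expression: design construction, dispersion estimation
and per-contrast likelihood-ratio testing.

Each conditioned group (conditioning type x time point) is compared to
the unconditioned reference under a negative-binomial GLM with log link,
log library-size offset, additive replicate (block) effects and a
trended dispersion evaluated per transcript. Each contrast is tested by
a likelihood-ratio test (full model vs the model without that group's
indicator column), with the p-value from a chi-square with one degree
of freedom. Significance is the raw p-value against alpha, matching the
source protocol; Benjamini-Hochberg adjustment is available but off by
default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from .nbglm import adjusted_profile_loglik, fit_nbglm

logger = logging.getLogger(__name__)

LN2 = float(np.log(2.0))


class DesignError(ValueError):
    pass


@dataclass
class DesignSpec:
    """Full-rank indicator design: intercept (unconditioned reference),
    replicate-block columns, one column per conditioned group."""

    samples: list[str]
    matrix: np.ndarray
    column_names: list[str]
    contrasts: list[tuple[str, str]]      # (conditioning_type, time_point)
    contrast_columns: dict[tuple[str, str], int]
    reference: str

    @property
    def n_params(self) -> int:
        return self.matrix.shape[1]


@dataclass
class DispersionModel:
    common_dispersion: float
    trend: Callable[[np.ndarray], np.ndarray]
    per_transcript: pd.Series
    ave_log_cpm: pd.Series = field(default_factory=pd.Series)


@dataclass(frozen=True)
class DECall:
    transcript_id: str
    conditioning_type: str
    time_point: str
    logfc: float
    p_value: float
    direction: str
    significant: bool


def residual_df(n_samples: int, n_condition_classes: int) -> int:
    """Residual degrees of freedom of the dispersion fit: samples minus
    condition classes (e.g. 12 samples over four classes leave 8)."""
    if n_condition_classes < 1:
        raise DesignError("n_condition_classes must be >= 1")
    df = n_samples - n_condition_classes
    if df <= 0:
        raise DesignError(
            f"nonpositive residual df: {n_samples} samples, "
            f"{n_condition_classes} condition classes"
        )
    return df


def build_design(
    meta: pd.DataFrame, unconditioned_label: str = "unconditioned"
) -> DesignSpec:
    """Build the blocked one-way design from sample metadata.

    ``meta`` needs columns sample_id, species, conditioning_type,
    time_point, replicate, for a single species including unconditioned
    samples. Groups are (conditioning_type, time_point) levels with the
    unconditioned group as reference; replicates enter as additive block
    columns (first replicate absorbed by the intercept).
    """
    required = {"sample_id", "species", "conditioning_type", "time_point", "replicate"}
    missing = required - set(meta.columns)
    if missing:
        raise DesignError(f"sample metadata missing columns: {sorted(missing)}")
    species = meta["species"].unique()
    if len(species) != 1:
        raise DesignError(f"one species at a time (got {list(species)})")
    is_ref = meta["conditioning_type"] == unconditioned_label
    if not is_ref.any():
        raise DesignError(f"no {unconditioned_label!r} samples in metadata")

    groups = sorted(
        {
            (str(ct), str(tp))
            for ct, tp in zip(meta["conditioning_type"], meta["time_point"])
            if ct != unconditioned_label
        }
    )
    if not groups:
        raise DesignError("design has no conditioned group to contrast")
    blocks = sorted(meta["replicate"].astype(str).unique())

    n = len(meta)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]
    for b in blocks[1:]:
        cols.append((meta["replicate"].astype(str) == b).to_numpy(float))
        names.append(f"block_{b}")
    contrast_columns: dict[tuple[str, str], int] = {}
    for ct, tp in groups:
        ind = (
            (meta["conditioning_type"].astype(str) == ct)
            & (meta["time_point"].astype(str) == tp)
        ).to_numpy(float)
        contrast_columns[(ct, tp)] = len(cols)
        cols.append(ind)
        names.append(f"group_{ct}_{tp}")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError("design matrix is rank deficient")
    return DesignSpec(
        samples=[str(s) for s in meta["sample_id"]],
        matrix=X,
        column_names=names,
        contrasts=groups,
        contrast_columns=contrast_columns,
        reference=unconditioned_label,
    )


def ave_log_cpm(counts: pd.DataFrame, prior: float = 0.25) -> pd.Series:
    """Average abundance per transcript, log2 counts-per-million with a
    small prior to keep zeros finite."""
    lib = counts.sum(axis=0).to_numpy(float)
    c = counts.to_numpy(float)
    avg = ((c + prior) / (lib + 2 * prior) * 1e6).mean(axis=1)
    return pd.Series(np.log2(avg), index=counts.index)


def _moment_dispersions(
    Y: np.ndarray, X: np.ndarray, offset: np.ndarray, working_phi: float = 0.0
) -> np.ndarray:
    """Method-of-moments dispersion per transcript: solves
    sum((y-mu)^2 - mu) = phi * sum(mu^2) at GLM-fitted means, with
    squared residuals deflated by their hat values. The working
    dispersion sets the fit weights; matching it to the data (e.g. the
    common-dispersion estimate) keeps the leverage correction accurate
    when library sizes vary strongly across samples."""
    _, _, mu, _ = fit_nbglm(Y, X, offset, working_phi)
    W = mu / (1.0 + working_phi * mu)
    XtWX = np.einsum("ni,tn,nj->tij", X, W, X) + 1e-10 * np.eye(X.shape[1])
    XtWXi = np.linalg.inv(XtWX)
    M = np.einsum("ni,tij->tnj", X, XtWXi)
    h = np.clip(W * np.einsum("tnj,nj->tn", M, X), 0.0, 0.95)
    num = ((Y - mu) ** 2 / (1.0 - h) - mu).sum(axis=1)
    den = (mu**2).sum(axis=1)
    return np.clip(num / np.clip(den, 1e-12, None), 0.0, None)


def estimate_dispersions(
    counts: pd.DataFrame,
    design: DesignSpec,
    lowess_frac: float = 0.3,
    min_dispersion: float = 1e-6,
) -> DispersionModel:
    """Estimate a common and a trended NB dispersion.

    The common dispersion maximises the summed Cox-Reid adjusted profile
    likelihood over all transcripts. The trend is a lowess local-mean
    smooth of per-transcript moment estimates over average log2-CPM,
    evaluated at each transcript's abundance (no tagwise shrinkage).
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    Y = counts.to_numpy(float)
    if Y.shape[0] < 1:
        raise DesignError("empty count matrix")
    if Y.shape[1] < design.n_params:
        raise DesignError("fewer samples than design parameters")
    X = design.matrix
    offset = np.log(np.clip(Y.sum(axis=0), 1.0, None))
    nonzero = Y.sum(axis=1) > 0
    Ynz = Y[nonzero]

    state: dict = {"beta": None}

    def neg_apl(log_phi: float) -> float:
        apl, beta = adjusted_profile_loglik(
            Ynz, X, offset, float(np.exp(log_phi)), beta0=state["beta"]
        )
        state["beta"] = beta
        return -apl

    res = minimize_scalar(
        neg_apl,
        bounds=(np.log(1e-6), np.log(10.0)),
        method="bounded",
        options={"xatol": 1e-3},
    )
    common = float(np.exp(res.x))

    abundance = ave_log_cpm(counts)
    phi_mom = np.full(Y.shape[0], np.nan)
    phi_mom[nonzero] = _moment_dispersions(Ynz, X, offset, working_phi=common)
    ok = nonzero & np.isfinite(phi_mom)
    xs = abundance.to_numpy()[ok]
    ys = phi_mom[ok]
    order = np.argsort(xs, kind="mergesort")
    smoothed = lowess(
        ys[order], xs[order], frac=lowess_frac, it=0, return_sorted=True
    )
    grid_x = smoothed[:, 0]
    grid_y = np.clip(smoothed[:, 1], min_dispersion, None)
    # local-linear fits extrapolate poorly at the abundance extremes,
    # where the moment estimates are also noisiest; evaluate from the
    # interior fit and extend it flat beyond the 5th/95th percentile
    if len(grid_x) >= 40:
        lo_q, hi_q = np.quantile(grid_x, [0.05, 0.95])
        interior = (grid_x >= lo_q) & (grid_x <= hi_q)
        grid_x, grid_y = grid_x[interior], grid_y[interior]

    def trend(a: np.ndarray) -> np.ndarray:
        return np.clip(
            np.interp(np.asarray(a, float), grid_x, grid_y),
            min_dispersion,
            None,
        )

    per = pd.Series(trend(abundance.to_numpy()), index=counts.index)
    return DispersionModel(
        common_dispersion=common,
        trend=trend,
        per_transcript=per,
        ave_log_cpm=abundance,
    )


def _dispersion_array(
    counts: pd.DataFrame,
    dispersions: DispersionModel | Mapping[str, float] | pd.Series | float,
) -> np.ndarray:
    if isinstance(dispersions, DispersionModel):
        ser = dispersions.per_transcript
    elif isinstance(dispersions, pd.Series):
        ser = dispersions
    elif isinstance(dispersions, Mapping):
        ser = pd.Series(dispersions)
    else:
        return np.full(counts.shape[0], float(dispersions))
    missing = counts.index.difference(ser.index)
    if len(missing):
        raise DesignError(
            f"dispersions missing for {len(missing)} transcripts, "
            f"e.g. {list(missing[:3])}"
        )
    return ser.reindex(counts.index).to_numpy(float)


def fit_and_test(
    counts: pd.DataFrame,
    design: DesignSpec,
    dispersions: DispersionModel | Mapping[str, float] | pd.Series | float,
    alpha: float = 0.05,
    bh: bool = False,
    max_iter: int = 100,
    tol: float = 1e-8,
    library_sizes: np.ndarray | None = None,
) -> tuple[list[DECall], list[str]]:
    """Fit the full NB GLM per transcript and LRT-test every contrast.

    Returns (calls, flagged) where ``flagged`` lists transcripts whose
    fit did not converge within the iteration cap; those transcripts are
    excluded from the calls. All-zero transcripts are reported with
    logFC 0 and p 1 for every contrast. With ``bh=True`` significance
    uses Benjamini-Hochberg adjusted p-values per contrast (the reported
    p_value stays raw). ``library_sizes`` overrides the default offset
    (the column sums of ``counts``) with known effective library sizes.
    """
    if list(counts.columns) != list(design.samples):
        raise DesignError("count matrix columns do not match design samples")
    Y = counts.to_numpy(float)
    X = design.matrix
    if library_sizes is None:
        library_sizes = np.clip(Y.sum(axis=0), 1.0, None)
    offset = np.log(np.asarray(library_sizes, dtype=float))
    phi = _dispersion_array(counts, dispersions)
    ids = list(counts.index.astype(str))

    nonzero = Y.sum(axis=1) > 0
    Ynz = Y[nonzero]
    phinz = phi[nonzero]

    beta_full, ll_full, _, conv_full = fit_nbglm(
        Ynz, X, offset, phinz, max_iter=max_iter, tol=tol
    )
    bad = ~conv_full
    stats = {}
    for contrast in design.contrasts:
        j = design.contrast_columns[contrast]
        keep = [k for k in range(X.shape[1]) if k != j]
        Xr = X[:, keep]
        beta0 = beta_full[:, keep]
        _, ll_red, _, conv_red = fit_nbglm(
            Ynz, Xr, offset, phinz, max_iter=max_iter, tol=tol, beta0=beta0
        )
        bad |= ~conv_red
        lrt = np.clip(2.0 * (ll_full - ll_red), 0.0, None)
        pvals = chi2.sf(lrt, df=1)
        logfc = beta_full[:, j] / LN2
        stats[contrast] = (logfc, pvals)

    nz_ids = [tid for tid, m in zip(ids, nonzero) if m]
    flagged = [tid for tid, b in zip(nz_ids, bad) if b]
    if flagged:
        logger.warning(
            "%d transcripts failed to converge and were excluded: %s%s",
            len(flagged),
            flagged[:5],
            "..." if len(flagged) > 5 else "",
        )
    keep_mask = ~bad

    calls: list[DECall] = []
    for contrast in design.contrasts:
        ct, tp = contrast
        logfc, pvals = stats[contrast]
        logfc, pvals = logfc[keep_mask], pvals[keep_mask]
        sig = _significance(pvals, alpha, bh)
        for tid, lf, p, s in zip(
            np.array(nz_ids)[keep_mask], logfc, pvals, sig
        ):
            calls.append(
                DECall(
                    transcript_id=str(tid),
                    conditioning_type=ct,
                    time_point=tp,
                    logfc=float(lf),
                    p_value=float(p),
                    direction="up" if lf >= 0 else "down",
                    significant=bool(s),
                )
            )
        for tid, z in zip(ids, nonzero):
            if not z:
                calls.append(
                    DECall(
                        transcript_id=tid,
                        conditioning_type=ct,
                        time_point=tp,
                        logfc=0.0,
                        p_value=1.0,
                        direction="up",
                        significant=False,
                    )
                )
    return calls, flagged


def _significance(pvals: np.ndarray, alpha: float, bh: bool) -> np.ndarray:
    if not bh:
        return pvals < alpha
    from statsmodels.stats.multitest import multipletests

    if len(pvals) == 0:
        return np.zeros(0, dtype=bool)
    reject, _, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return reject


def calls_to_dataframe(calls: Sequence[DECall]) -> pd.DataFrame:
    return pd.DataFrame(
        [c.__dict__ for c in calls],
        columns=[
            "transcript_id",
            "conditioning_type",
            "time_point",
            "logfc",
            "p_value",
            "direction",
            "significant",
        ],
    )


def dataframe_to_calls(df: pd.DataFrame) -> list[DECall]:
    return [
        DECall(
            transcript_id=str(r.transcript_id),
            conditioning_type=str(r.conditioning_type),
            time_point=str(r.time_point),
            logfc=float(r.logfc),
            p_value=float(r.p_value),
            direction=str(r.direction),
            significant=bool(r.significant),
        )
        for r in df.itertuples(index=False)
    ]
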