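"""Evaluation metrics and replicated scenario experiments.

Prediction quality is summarized the standard way for breeding-value
validation: accuracy = Pearson correlation between true (TBV) and
estimated (EBV) breeding values, and dispersion bias = slope of the
regression of TBV on EBV (1 means no over/under-dispersion; < 1 means
EBV are over-dispersed).

``run_experiment`` repeats simulate -> fit -> evaluate for one of the
methods (simple pedigree BLUP ignoring genotypes, GCMTBLUP with
REML-estimated or known components, Gengler imputation + covariate
model, iterative peeling + covariate model) and reports, per
replicate, the trait and gene-content accuracies/slopes for the
final-generation selection candidates and for phenotyped females of
the previous generation, plus the substitution-effect estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .competitors import CovariateModel, GenglerImputation, IterativePeeling
from .gcmt import GeneContentBLUP, GeneContentREML
from .mme import animal_model_blup
from .pedigree import additive_relationship_inverse
from .simulate import ScenarioConfig, simulate_scenario

__all__ = ["EvaluationResult", "accuracy_and_slope", "run_experiment", "METHODS"]

METHODS = ("simple_blup", "gcmtblup", "gengler", "peeling")


@dataclass
class EvaluationResult:
    """Accuracy and dispersion of EBV against TBV for one group."""

    group: str
    n: int
    accuracy: float
    slope: float


def accuracy_and_slope(tbv, ebv, group: str = "") -> EvaluationResult:
    """Correlation(TBV, EBV) and regression slope of TBV on EBV."""
    tbv = np.asarray(tbv, dtype=float)
    ebv = np.asarray(ebv, dtype=float)
    if tbv.shape != ebv.shape or tbv.ndim != 1 or tbv.size < 3:
        raise ValueError("need two equal-length vectors with >= 3 entries")
    v = ebv.var(ddof=1)
    if v <= 0:
        raise ValueError("EBV variance is zero: slope undefined")
    acc = float(np.corrcoef(tbv, ebv)[0, 1])
    slope = float(np.cov(tbv, ebv)[0, 1] / v)
    return EvaluationResult(group, tbv.size, acc, slope)


def _fit_method(method, pop, rec, ainv, reml, reml_kw):
    """Fit one method; returns (u_y, z_pred, alpha_hat, reml_fit)."""
    cfg = pop.config
    if method == "simple_blup":
        s2u = cfg.h2_total * cfg.phenotypic_variance
        _, u, _ = animal_model_blup(pop.pedigree, rec.y, s2u, cfg.sigma2_e,
                                    ainv=ainv)
        return u, None, np.nan, None
    if method == "gcmtblup":
        fit = None
        if reml:
            fit = GeneContentREML(**reml_kw).fit(pop.pedigree, rec, ainv=ainv)
            g0, s2ey = fit.g0_, fit.sigma2_ey_
            alpha = fit.estimates_.alpha
        else:
            g0, s2ey = cfg.g0(), cfg.sigma2_e
            alpha = cfg.alpha
        est = GeneContentBLUP(g0=g0, sigma2_ey=s2ey).fit(pop.pedigree, rec,
                                                         ainv=ainv)
        return est.u_y_, est.predict_gene_content(), alpha, fit
    if method == "gengler":
        imp = GenglerImputation().fit(pop.pedigree, rec.z[:, 0], ainv=ainv)
        zhat = imp.z_hat_
    elif method == "peeling":
        peel = IterativePeeling().fit(pop.pedigree, rec.z[:, 0])
        zhat = np.where(np.isnan(rec.z[:, 0]), peel.expected_content_,
                        rec.z[:, 0])
    else:
        raise ValueError(f"unknown method {method!r}")
    cov = CovariateModel(cfg.sigma2_eps, cfg.sigma2_e).fit(
        pop.pedigree, rec.y, zhat, ainv=ainv
    )
    return cov.u_y_, zhat, cov.alpha_, None


def run_experiment(
    cfg: ScenarioConfig,
    method: str,
    replicates: int = 10,
    seed: int | None = None,
    reml: bool = True,
    reml_kw: dict | None = None,
) -> pd.DataFrame:
    """Replicated simulate -> fit -> evaluate for one method.

    Returns a tidy frame with one row per replicate x group; group
    "candidates" = final-generation males, "females" = phenotyped
    females of the preceding generation.  Gene-content metrics are
    computed over the non-genotyped animals of each group (prediction
    of observed genotypes is trivial).  A method failure in a replicate
    is recorded (NaN metrics), not fatal.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    reml_kw = dict(reml_kw or {})
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=replicates)
    rows = []
    for rep, rs in enumerate(rep_seeds):
        pop = simulate_scenario(cfg, seed=int(rs))
        rec = pop.records()
        ainv = additive_relationship_inverse(pop.pedigree)
        try:
            u_y, z_pred, alpha_hat, fit = _fit_method(
                method, pop, rec, ainv, reml, reml_kw
            )
            err = ""
        except Exception as e:  # noqa: BLE001 - record, don't kill the sweep
            rows.extend(
                {
                    "replicate": rep, "seed": int(rs), "method": method,
                    "group": grp, "n": 0, "trait_accuracy": np.nan,
                    "trait_slope": np.nan, "content_accuracy": np.nan,
                    "content_slope": np.nan, "alpha_hat": np.nan,
                    "error": repr(e),
                }
                for grp in ("candidates", "females")
            )
            continue
        tbv = pop.tbv
        tz = pop.z
        genotyped = ~np.isnan(rec.z[:, 0])
        for grp, idx in (
            ("candidates", pop.candidates()),
            ("females", pop.phenotyped_females()),
        ):
            r = accuracy_and_slope(tbv[idx], u_y[idx], grp)
            crow = {"content_accuracy": np.nan, "content_slope": np.nan}
            if z_pred is not None:
                ng = idx[~genotyped[idx]]
                if ng.size >= 3 and np.ptp(z_pred[ng]) > 1e-12:
                    cr = accuracy_and_slope(tz[ng], z_pred[ng])
                    crow = {
                        "content_accuracy": cr.accuracy,
                        "content_slope": cr.slope,
                    }
            rows.append(
                {
                    "replicate": rep, "seed": int(rs), "method": method,
                    "group": grp, "n": r.n, "trait_accuracy": r.accuracy,
                    "trait_slope": r.slope, **crow, "alpha_hat": alpha_hat,
                    "error": err,
                }
            )
    return pd.DataFrame(rows)
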