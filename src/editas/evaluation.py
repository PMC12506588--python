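"""Simulation studies validating the statistical machinery.

These routines generate data directly from the model distributions (not via
the file-based cohort generator) and measure operating characteristics:
type-I error and p-value uniformity of the beta-binomial LLR test, power and
parameter recovery at planted effect sizes, the differential-splicing test's
calibration, editing-PSI coupling recovery, and the motif-delta classifier's
sensitivity/false-alteration rate.  They are used by the test suite and by
``scripts/acceptance.py``; sizes default to the study conditions they probe.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from . import associate, diffedit, rbp, splicing
from .simulate import sample_betabinom


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), 100 + stream])


def _truncated_poisson(rng, lam, size):
    x = rng.poisson(lam, size=size)
    while (x == 0).any():
        zero = x == 0
        x[zero] = rng.poisson(lam, size=int(zero.sum()))
    return x


def _simulate_group(rng, n_samples, mu, phi, mean_cov):
    cov = _truncated_poisson(rng, mean_cov, n_samples)
    k = sample_betabinom(rng, cov, mu, phi)
    return k, cov


# ---------------------------------------------------------------------------
# Beta-binomial LLR test

def _count_frame(k1, c1, k2, c2):
    """Assemble (edited, coverage) arrays into a count table + design."""
    from .io import SampleDesign

    n_sites = k1.shape[0]
    df = pd.DataFrame({
        "chrom": "chr1", "pos": np.arange(1, n_sites + 1),
        "ref": "A", "alt": "G", "strand": "+",
    })
    samples_a = [f"UIA_{j + 1}" for j in range(k1.shape[1])]
    samples_b = [f"RIA_{j + 1}" for j in range(k2.shape[1])]
    for j, s in enumerate(samples_a):
        df[f"cov_{s}"] = c1[:, j]
        df[f"alt_{s}"] = k1[:, j]
    for j, s in enumerate(samples_b):
        df[f"cov_{s}"] = c2[:, j]
        df[f"alt_{s}"] = k2[:, j]
    df.index = pd.Index([f"chr1:{p}:A>G" for p in df["pos"]], name="site_id")
    design = SampleDesign(
        {**{s: "UIA" for s in samples_a}, **{s: "RIA" for s in samples_b}}
    )
    return df, design


def _simulate_count_matrix(rng, n_sites, n_samples, mu, phi, mean_cov):
    cov = _truncated_poisson(rng, mean_cov, n_sites * n_samples).reshape(
        n_sites, n_samples
    )
    if phi < 1e-8:
        p = np.full((n_sites, n_samples), mu)
    else:
        p = rng.beta(mu / phi, (1 - mu) / phi, size=(n_sites, n_samples))
    return rng.binomial(cov, p), cov


def betabinom_null_calibration(
    n_sites: int = 2000,
    mu: float = 0.3,
    phi: float = 0.1,
    n1: int = 8,
    n2: int = 5,
    mean_coverage: float = 50.0,
    alpha: float = 0.05,
    seed: int = 1,
) -> dict:
    """Empirical size and p-value uniformity of the two-group differential
    editing test under a shared (mu, phi)."""
    rng = _rng(seed, 1)
    k1, c1 = _simulate_count_matrix(rng, n_sites, n1, mu, phi, mean_coverage)
    k2, c2 = _simulate_count_matrix(rng, n_sites, n2, mu, phi, mean_coverage)
    df, design = _count_frame(k1, c1, k2, c2)
    res = diffedit.test_differential_editing(df, design)
    pvals = res.loc[res["status"] == "ok", "pvalue"].to_numpy()
    ks = stats.kstest(pvals, "uniform")
    return {
        "alpha_hat": float(np.mean(pvals < alpha)),
        "ks_distance": float(ks.statistic),
        "pvalues": pvals,
    }


def diffedit_power(
    n_sites: int = 500,
    mu1: float = 0.2,
    mu2: float = 0.4,
    phi: float = 0.02,
    n1: int = 8,
    n2: int = 5,
    coverage: float = 100.0,
    min_delta: float = 0.05,
    alpha: float = 0.05,
    seed: int = 1,
) -> float:
    """Fraction of planted differential sites called at the standard
    thresholds (|delta| >= 0.05 and p < 0.05)."""
    rng = _rng(seed, 2)
    k1, c1 = _simulate_count_matrix(rng, n_sites, n1, mu1, phi, coverage)
    k2, c2 = _simulate_count_matrix(rng, n_sites, n2, mu2, phi, coverage)
    df, design = _count_frame(k1, c1, k2, c2)
    res = diffedit.test_differential_editing(df, design)
    called = diffedit.call_dres(res, min_delta, alpha)
    return len(called) / n_sites


def editing_level_recovery(
    n_sites: int = 1000,
    n_samples: int = 13,
    coverage: float = 100.0,
    phi: float = 0.02,
    mus: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5),
    seed: int = 1,
) -> dict:
    """Mean absolute error of the fitted mean editing level over sites drawn
    from a grid of true levels."""
    rng = _rng(seed, 3)
    errors = np.empty(n_sites)
    mu_true = np.asarray(mus)[rng.integers(0, len(mus), n_sites)]
    for i in range(n_sites):
        k, c = _simulate_group(rng, n_samples, float(mu_true[i]), phi,
                               coverage)
        fit = diffedit.fit_betabinom(k, c)
        errors[i] = abs(fit.mu - mu_true[i])
    return {"mae": float(errors.mean()), "errors": errors}


# ---------------------------------------------------------------------------
# Differential splicing

def _splice_table(inc_a, inc_b, depth, li=2, ls=1):
    n_events = inc_a.shape[0]
    samples = [f"A{j}" for j in range(inc_a.shape[1])] + [
        f"B{j}" for j in range(inc_b.shape[1])
    ]
    df = pd.DataFrame({
        "event_id": [f"E{i}" for i in range(n_events)],
        "type": "SE", "gene_id": "G", "chrom": "chr1", "strand": "+",
        "coords": "1,2", "len_inc": li, "len_skip": ls,
    })
    inc = np.concatenate([inc_a, inc_b], axis=1)
    for j, s in enumerate(samples):
        df[f"inc_{s}"] = inc[:, j]
        df[f"skip_{s}"] = depth - inc[:, j]
    groups = {f"A{j}": "UIA" for j in range(inc_a.shape[1])}
    groups.update({f"B{j}": "RIA" for j in range(inc_b.shape[1])})
    from .io import SampleDesign

    return df.set_index("event_id", drop=False), SampleDesign(groups)


def _inclusion_prob(psi, li, ls):
    return psi * li / (psi * li + (1 - psi) * ls)


def splicing_null_calibration(
    n_events: int = 2000,
    psi: float = 0.5,
    depth: int = 200,
    n1: int = 8,
    n2: int = 5,
    alpha: float = 0.05,
    seed: int = 1,
) -> dict:
    """Empirical size of the binomial group-term LRT on null events."""
    rng = _rng(seed, 4)
    p = _inclusion_prob(psi, 2, 1)
    inc_a = rng.binomial(depth, p, size=(n_events, n1))
    inc_b = rng.binomial(depth, p, size=(n_events, n2))
    df, design = _splice_table(inc_a, inc_b, depth)
    res = splicing.differential_splicing(df, design)
    pvals = res["pvalue"].to_numpy()
    return {
        "alpha_hat": float(np.mean(pvals < alpha)),
        "pvalues": pvals,
    }


def splicing_power(
    n_events: int = 500,
    psi_a: float = 0.35,
    psi_b: float = 0.65,
    depth: int = 200,
    n1: int = 8,
    n2: int = 5,
    min_dpsi: float = 0.1,
    max_fdr: float = 0.05,
    seed: int = 1,
) -> float:
    """Fraction of planted differential events surviving the |dPSI| and FDR
    thresholds (FDR taken over the planted set itself)."""
    rng = _rng(seed, 5)
    inc_a = rng.binomial(depth, _inclusion_prob(psi_a, 2, 1),
                         size=(n_events, n1))
    inc_b = rng.binomial(depth, _inclusion_prob(psi_b, 2, 1),
                         size=(n_events, n2))
    df, design = _splice_table(inc_a, inc_b, depth)
    res = splicing.differential_splicing(df, design)
    called, _ = splicing.call_dase(res, min_dpsi, max_fdr)
    return len(called) / n_events


def psi_recovery(
    n_events: int = 500,
    depth: int = 200,
    psis: tuple[float, ...] = (0.2, 0.35, 0.5, 0.65, 0.8),
    li: int = 2,
    ls: int = 1,
    seed: int = 1,
) -> dict:
    """Mean absolute error of single-sample PSI estimates."""
    rng = _rng(seed, 6)
    psi_true = np.asarray(psis)[rng.integers(0, len(psis), n_events)]
    inc = rng.binomial(depth, _inclusion_prob(psi_true, li, ls))
    est = np.array(
        [splicing.compute_psi(int(i), int(depth - i), li, ls) for i in inc]
    )
    return {"mae": float(np.mean(np.abs(est - psi_true)))}


# ---------------------------------------------------------------------------
# Editing-PSI coupling

def coupling_recovery(
    n_reps: int = 300,
    slope: float = 4.0,
    depth: int = 200,
    mu: float = 0.4,
    phi: float = 0.1,
    psi0: float = 0.5,
    mean_coverage: float = 50.0,
    n_samples: int = 13,
    min_abs_r: float = 0.5,
    alpha: float = 0.05,
    seed: int = 1,
) -> float:
    """Fraction of replicates where a coupled site-event pair passes the
    |r| > 0.5, p < 0.05 filter (slope 0 gives the null pass rate)."""
    rng = _rng(seed, 7)
    passed = 0
    li, ls = 2, 1
    for _ in range(n_reps):
        cov = _truncated_poisson(rng, mean_coverage, n_samples)
        if phi < 1e-8:
            p_edit = np.full(n_samples, mu)
        else:
            p_edit = rng.beta(mu / phi, (1 - mu) / phi, n_samples)
        k = rng.binomial(cov, p_edit)
        e_hat = k / cov
        psi_s = expit(logit(psi0) + slope * (e_hat - mu))
        inc = rng.binomial(depth, _inclusion_prob(psi_s, li, ls))
        psi_hat = (inc / li) / (inc / li + (depth - inc) / ls)
        try:
            r, p, _ = associate.correlate(e_hat, psi_hat)
        except Exception:
            continue
        if abs(r) > min_abs_r and p < alpha:
            passed += 1
    return passed / n_reps


# ---------------------------------------------------------------------------
# RBP motif deltas

def motif_disruption_performance(
    cohort_dir,
    threshold: float = 0.20,
) -> dict:
    """Sensitivity on planted disruptions and false-alteration rate on
    unplanned site-RBP combinations, from a generated cohort directory."""
    import json
    from pathlib import Path

    from . import io as eio

    cohort_dir = Path(cohort_dir)
    with open(cohort_dir / "truth.json") as fh:
        truth = json.load(fh)
    genome = eio.read_fasta(cohort_dir / "genome.fa")
    counts = eio.read_count_table(cohort_dir / "counts.tsv")
    motifs = rbp.read_pwms(cohort_dir / "motifs.pwm")
    ag = counts[[r == "A" and a == "G" or r == "T" and a == "C"
                 for r, a in zip(counts["ref"], counts["alt"])]]
    deltas = rbp.scan_cohort(ag, genome, motifs, threshold=threshold)
    planned = {(p["site_id"], p["rbp"]): p["sign"]
               for p in truth["motif_plan"]}
    is_planned = [
        (s, b) in planned for s, b in zip(deltas["site_id"], deltas["rbp"])
    ]
    deltas = deltas.assign(planned=is_planned)
    plan_rows = deltas[deltas["planned"]]
    other_rows = deltas[~deltas["planned"]]
    sign_ok = [
        (d < 0 if planned[(s, b)] == "loss" else d > 0)
        for s, b, d in zip(plan_rows["site_id"], plan_rows["rbp"],
                           plan_rows["delta"])
    ]
    sensitivity = float(np.mean(plan_rows["altered"].to_numpy()
                                & np.asarray(sign_ok)))
    false_rate = float(other_rows["altered"].mean()) if len(other_rows) else 0.0
    return {
        "sensitivity": sensitivity,
        "false_alteration_rate": false_rate,
        "n_planned": int(len(plan_rows)),
        "n_other": int(len(other_rows)),
    }
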