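"""Canned simulation scenarios for recovery analyses.

Each function returns a :class:`SimulationConfig` describing one study
condition:

* :func:`mutagenesis` — the methylome-tier mutagenesis sweep: exon
  lengths match the methylome datasets' averages (~650 bp), selection
  is disabled, and the methylated-CpG C->T multiplier lambda varies.
  Used to recover the negative Pearson r(mCG density, CpG O/E) and its
  monotone strengthening with lambda.
* :func:`selection_ordering` — per-class nonsynonymous acceptance
  ordered first > last > internal (0.9 / 0.6 / 0.3), recovering the
  observed rate ordering across position classes.
* :func:`mediation` — a covariate (disorder proportion) tracks exon
  length and drives nonsynonymous acceptance, so the length–rate
  association is fully mediated; the control analysis should attenuate
  it.  With ``mediated=False`` the length effect is direct and the
  covariates are independent noise, so plain and partial correlations
  should agree.
* :func:`neutral` — selection and methylation mutagenesis disabled
  (acceptance 1, lambda 1); median omega should be near 1.
"""

from __future__ import annotations

from .simulate import SimulationConfig


def mutagenesis(cpg_lambda: float, seed: int = 0, n_genes: int = 500) -> SimulationConfig:
    return SimulationConfig(
        n_genes=n_genes,
        exon_count_mean=4.0,
        exon_length_mean={"first": 650.0, "last": 650.0, "internal": 650.0},
        acceptance={"first": 1.0, "last": 1.0, "internal": 1.0},
        cpg_lambda=cpg_lambda,
        seed=seed,
    )


def selection_ordering(seed: int = 0, n_genes: int = 500) -> SimulationConfig:
    return SimulationConfig(
        n_genes=n_genes,
        exon_count_mean=3.0,
        acceptance={"first": 0.9, "last": 0.6, "internal": 0.3},
        cpg_lambda=1.0,
        seed=seed,
    )


def mediation(seed: int = 0, mediated: bool = True, n_genes: int = 700) -> SimulationConfig:
    common = dict(
        n_genes=n_genes,
        exon_count_mean=3.0,
        exon_length_sigma=0.6,
        acceptance={"first": 0.5, "last": 0.5, "internal": 0.5},
        cpg_lambda=1.0,
        seed=seed,
    )
    if mediated:
        return SimulationConfig(
            disorder_length_effect=2.5,
            accept_disorder_effect=1.5,
            **common,
        )
    return SimulationConfig(accept_length_effect=1.0, **common)


def neutral(seed: int = 0, n_genes: int = 250) -> SimulationConfig:
    return SimulationConfig(
        n_genes=n_genes,
        exon_count_mean=3.0,
        acceptance={"first": 1.0, "last": 1.0, "internal": 1.0},
        cpg_lambda=1.0,
        seed=seed,
    )
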