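"""Replicated simulation studies: type-I error, power, sign accuracy, and
marginal-filter quality.

A study is a pure function of its configuration: every replicate derives its
random streams from ``(master_seed, scenario_id, replicate_index)``, so two
runs of the same :class:`StudyConfig` are bit-identical.  Each replicate
draws a fresh LD-structured gene, assigns four causal SNPs, samples effect
sizes and the exposure, simulates the trait, and applies every requested
test to the same data.

Metric conventions:

* *rejection rate* — fraction of replicates with interaction p < alpha;
* *power* — for the directional tests (ridge/lasso/enet GRS and SBERIA),
  rejection AND the correct sign of the interaction coefficient; for the
  variance-component and ADABF tests, rejection alone (they claim no
  direction).  In cross-over scenarios the true sign is undefined and power
  reduces to the rejection rate for every method;
* *sign misspecification* — wrong-signed rejections as a fraction of all
  rejections (undefined for cross-over scenarios and when nothing rejects);
* *SEN / PPV* — of the marginal filtering stage, against the 4 causal SNPs:
  SEN = |selected ∩ causal| / 4, PPV = |selected ∩ causal| / |selected|.
  The selected set is the nonzero-weight set for lasso/enet and the
  p < 0.1 set for SBERIA (the tiny nu offset does not count as selection).

All rate estimates carry Wilson 95% confidence intervals.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .comparators import adabf_test, iskat_test, sberia_test
from .data_io import CohortTable, GenotypePanel
from .grs_gxe import run_grs_pipeline
from .pheno_sim import (ScenarioSpec, get_scenario, sample_effects,
                        sample_exposure, simulate_trait)
from .synthetic_genotypes import (GenotypeSimConfig, LDBlockSpec,
                                  assign_causal_snps, simulate_ld_genotypes)

__all__ = [
    "StudyConfig",
    "StudySummary",
    "run_type1_study",
    "run_power_study",
    "sign_misspecification",
    "filter_metrics",
    "GRS_METHODS",
    "DIRECTIONAL_METHODS",
    "ALL_METHODS",
]

GRS_METHODS = ("ridge", "lasso", "enet")
DIRECTIONAL_METHODS = GRS_METHODS + ("sberia",)
ALL_METHODS = DIRECTIONAL_METHODS + ("iskat", "adabf")


@dataclass
class StudyConfig:
    """Everything that defines one simulation study."""

    methods: tuple[str, ...] = ("ridge",)
    trait_family: str = "gaussian"
    exposure_kind: str = "binary"        # binary | continuous
    p_exposed: float = 0.2
    prevalence: float = 0.1              # binomial traits only
    scenario_ids: tuple[int, ...] = (1,)
    gene_size: int = 48
    ld: LDBlockSpec | None = None
    n_subjects: int = 2000
    n_replicates: int = 2000
    alpha: float = 0.05
    master_seed: int = 0
    effect_scale: float = 1.0
    folds: int = 10
    adabf_prior_var: float = 0.04
    adabf_max_resamples: int = 1000

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        unknown = set(self.methods) - set(ALL_METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")


@dataclass
class StudySummary:
    """Per-method (x scenario) rates with Wilson confidence intervals."""

    table: pd.DataFrame
    replicates: pd.DataFrame
    config: StudyConfig

    def to_json(self) -> str:
        cfg = asdict(self.config)
        cfg["ld"] = None if self.config.ld is None else asdict(self.config.ld)
        return json.dumps({"config": cfg,
                           "table": self.table.to_dict(orient="records")},
                          default=float, indent=2)

    def rate(self, method: str, metric: str,
             scenario_id: int | None = None) -> float:
        t = self.table[self.table.method == method]
        if scenario_id is not None:
            t = t[t.scenario == scenario_id]
        return float(t[metric].iloc[0])


def filter_metrics(selected: np.ndarray,
                   causal: np.ndarray) -> tuple[float, float]:
    """(sensitivity, positive predictive value) of a selected-SNP set.

    PPV is NaN (undefined) when nothing was selected.
    """
    causal = np.asarray(causal, dtype=int)
    if causal.size != 4:
        raise ValueError("exactly 4 causal SNPs are expected")
    selected = np.asarray(selected, dtype=int)
    tp = np.intersect1d(selected, causal).size
    sen = tp / 4.0
    ppv = tp / selected.size if selected.size else float("nan")
    return sen, ppv


def sign_misspecification(p_values: np.ndarray, int_signs: np.ndarray,
                          scenario: ScenarioSpec,
                          alpha: float = 0.05) -> float:
    """Wrong-signed rejections / all rejections; NaN if nothing rejects.

    Refuses cross-over scenarios, where no true aggregate sign exists.
    """
    true_sign = scenario.true_int_sign
    if true_sign is None:
        raise ValueError(
            f"scenario {scenario.scenario_id} is cross-over: the true "
            "interaction sign is undefined")
    p_values = np.asarray(p_values, dtype=float)
    int_signs = np.asarray(int_signs, dtype=float)
    rej = p_values < alpha
    if not rej.any():
        return float("nan")
    wrong = rej & (int_signs != true_sign)
    return float(wrong.sum() / rej.sum())


# ---------------------------------------------------------------------------
# replicate machinery
# ---------------------------------------------------------------------------

def _derive_seeds(master_seed: int, scenario_id: int, rep: int,
                  k: int = 8) -> np.ndarray:
    ss = np.random.SeedSequence(entropy=(master_seed, scenario_id, rep))
    return ss.generate_state(k).astype(np.int64) % (2 ** 31)


def _run_replicate(config: StudyConfig, scenario: ScenarioSpec, rep: int,
                   null_interactions: bool) -> list[dict]:
    seeds = _derive_seeds(config.master_seed, scenario.scenario_id, rep,
                          k=5 + len(config.methods))
    panel = simulate_ld_genotypes(GenotypeSimConfig(
        n_subjects=config.n_subjects, gene_size=config.gene_size,
        ld=config.ld, seed=int(seeds[0])))
    causal = assign_causal_snps(panel, 4, seed=int(seeds[1]))
    effects = sample_effects(scenario, family=config.trait_family,
                             seed=int(seeds[2]), prevalence=config.prevalence,
                             effect_scale=config.effect_scale,
                             null_interactions=null_interactions)
    exposure = sample_exposure(config.exposure_kind, config.n_subjects,
                               p_exposed=config.p_exposed, seed=int(seeds[3]))
    sim = simulate_trait(panel, causal, effects, exposure,
                         seed=int(seeds[4]), scenario=scenario)
    cohort = sim.cohort

    rows = []
    for m, mseed in zip(config.methods, range(5, 5 + len(config.methods))):
        seed_m = int(seeds[mseed])
        row = {"scenario": scenario.scenario_id, "replicate": rep,
               "method": m, "sign": np.nan, "sen": np.nan, "ppv": np.nan}
        if m in GRS_METHODS:
            r = run_grs_pipeline(cohort, panel, method=m, seed=seed_m,
                                 alpha=config.alpha, folds=config.folds)
            row["p"] = r.p_value
            row["sign"] = np.sign(r.gamma_int_hat) if not r.degenerate else 0.0
            if m in ("lasso", "enet"):
                row["sen"], row["ppv"] = filter_metrics(
                    r.selected if r.selected is not None else np.array([]),
                    causal)
        elif m == "sberia":
            r = sberia_test(cohort, panel, alpha=config.alpha)
            row["p"] = r.p_value
            row["sign"] = np.sign(r.gamma_int_hat)
            row["sen"], row["ppv"] = filter_metrics(r.selected, causal)
        elif m == "iskat":
            r = iskat_test(cohort, panel, seed=seed_m, folds=config.folds)
            row["p"] = r.p_value
        elif m == "adabf":
            r = adabf_test(cohort, panel, prior_var=config.adabf_prior_var,
                           max_resamples=config.adabf_max_resamples,
                           seed=seed_m)
            row["p"] = r.p_value
        rows.append(row)
    return rows


def _summarize(reps: pd.DataFrame, config: StudyConfig,
               scenarios: dict[int, ScenarioSpec]) -> pd.DataFrame:
    out = []
    for (sc_id, m), grp in reps.groupby(["scenario", "method"], sort=True):
        scenario = scenarios[sc_id]
        n = len(grp)
        rej = (grp.p < config.alpha)
        true_sign = scenario.true_int_sign
        if m in DIRECTIONAL_METHODS and true_sign is not None:
            success = rej & (grp.sign == true_sign)
            sign_correct = float((grp.sign == true_sign).mean())
            misspec = (float((rej & (grp.sign != true_sign)).sum() / rej.sum())
                       if rej.any() else float("nan"))
        else:
            success = rej
            sign_correct = float("nan")
            misspec = float("nan")
        lo, hi = proportion_confint(int(success.sum()), n, method="wilson")
        rlo, rhi = proportion_confint(int(rej.sum()), n, method="wilson")
        out.append({
            "scenario": sc_id, "method": m, "label": scenario.label,
            "n_replicates": n,
            "rejection_rate": float(rej.mean()),
            "rejection_ci_low": float(rlo), "rejection_ci_high": float(rhi),
            "power": float(success.mean()),
            "power_ci_low": float(lo), "power_ci_high": float(hi),
            "sign_correct_rate": sign_correct,
            "sign_misspec_pct": misspec,
            "sen": float(grp.sen.mean()) if grp.sen.notna().any() else float("nan"),
            "ppv": float(grp.ppv.mean()) if grp.ppv.notna().any() else float("nan"),
        })
    return pd.DataFrame(out)


def _run_study(config: StudyConfig, null_interactions: bool) -> StudySummary:
    scenarios = {sid: get_scenario(sid) for sid in config.scenario_ids}
    rows: list[dict] = []
    for sid, scenario in scenarios.items():
        for rep in range(config.n_replicates):
            rows.extend(_run_replicate(config, scenario, rep,
                                       null_interactions))
    reps = pd.DataFrame(rows)
    return StudySummary(table=_summarize(reps, config, scenarios),
                        replicates=reps, config=config)


def run_type1_study(config: StudyConfig) -> StudySummary:
    """Empirical size: the scenario's interactions are all forced to zero.

    Everything else (main effects, exposure effect, LD, causal assignment)
    follows the scenario, so the generator is exactly the null of the
    interaction test.
    """
    return _run_study(config, null_interactions=True)


def run_power_study(config: StudyConfig) -> StudySummary:
    """Power, sign accuracy, and filter SEN/PPV under non-null scenarios."""
    return _run_study(config, null_interactions=False)


def plot_summary(summary: StudySummary, path: str,
                 metric: str = "power") -> None:
    """Simple grouped bar chart of a study metric (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = summary.table
    scenarios = sorted(t.scenario.unique())
    methods = list(dict.fromkeys(t.method))
    width = 0.8 / len(methods)
    fig, ax = plt.subplots(figsize=(1.5 + 1.2 * len(scenarios), 4))
    for i, m in enumerate(methods):
        sub = t[t.method == m].set_index("scenario").reindex(scenarios)
        ax.bar(np.arange(len(scenarios)) + i * width, sub[metric],
               width=width, label=m)
    ax.set_xticks(np.arange(len(scenarios)) + 0.4 - width / 2)
    ax.set_xticklabels([str(s) for s in scenarios])
    ax.set_xlabel("scenario")
    ax.set_ylabel(metric)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
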