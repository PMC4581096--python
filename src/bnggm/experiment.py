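"""End-to-end experiment orchestration.

Reproduces the standard comparison protocol: simulate (or load) replicate
data sets from a gold-standard network, compute the GGM guidance matrix tau
once per data set from that data set alone, run two independently seeded
chains per sampler mode, and summarize accuracy (mean +/- sd AUC versus
MCMC step across data sets) and convergence (c_rms versus step).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bge import BGeHyperparams
from .evaluation import auc_trajectory, crms_trajectory
from .ggm import compute_tau
from .graphs import DAG, random_dag, read_adjacency
from .networks import benchmark_dag
from .sampler import ChainTrace, SamplerConfig, run_chain
from .synthetic import Dataset, GaussianSimConfig, quantile_normalize, read_dataset, simulate_gaussian

__all__ = ["ExperimentPlan", "ExperimentResult", "run_experiment"]

MODES = ("bn", "bnggm")


@dataclass
class ExperimentPlan:
    """Everything needed to reproduce one experiment grid.

    ``data_type`` selects linear-Gaussian simulation from ``true_dag``
    (default: the packaged 10-node benchmark) or externally produced data
    files listed in ``external_data``; external data is quantile-normalized
    automatically, simulated Gaussian data never is.  Each of the
    ``n_datasets`` data sets is analysed by both sampler modes with
    ``chains_per_dataset`` independently seeded chains each, so the default
    plan runs 5 x 2 x 2 = 20 chains.
    """

    data_type: str = "gaussian"
    n_datasets: int = 5
    chains_per_dataset: int = 2
    true_dag: DAG | None = None
    sim: GaussianSimConfig = field(default_factory=GaussianSimConfig)
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    hyper: BGeHyperparams | None = None
    external_data: list[str] = field(default_factory=list)
    master_seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.data_type not in ("gaussian", "external"):
            raise ValueError("data_type must be 'gaussian' or 'external'")
        if self.chains_per_dataset < 2:
            raise ValueError("chains_per_dataset must be >= 2 for convergence reporting")
        if self.data_type == "external" and len(self.external_data) < 1:
            raise ValueError("data_type='external' requires external_data file paths")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentPlan":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "sim" in raw:
            raw["sim"] = GaussianSimConfig(**raw["sim"])
        if "sampler" in raw:
            raw["sampler"] = SamplerConfig(**raw["sampler"])
        if "hyper" in raw:
            raw["hyper"] = BGeHyperparams(**raw["hyper"])
        if "true_dag" in raw and isinstance(raw["true_dag"], str):
            raw["true_dag"] = read_adjacency(raw["true_dag"])
        return cls(**raw)


@dataclass
class ExperimentResult:
    """Summary tables plus the manifest and raw traces of one experiment."""

    auc_summary: pd.DataFrame
    crms_summary: pd.DataFrame
    manifest: dict
    traces: dict[tuple[int, str, int], ChainTrace]
    true_dag: DAG


def _chain_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _load_datasets(plan: ExperimentPlan, rng_seeds: list[int]) -> list[Dataset]:
    if plan.data_type == "gaussian":
        dag = plan.true_dag or benchmark_dag()
        return [
            simulate_gaussian(dag, replace(plan.sim, seed=s)) for s in rng_seeds
        ]
    data = [read_dataset(p) for p in plan.external_data[: plan.n_datasets]]
    return [quantile_normalize(d) for d in data]


def run_experiment(plan: ExperimentPlan) -> ExperimentResult:
    """Run the full experiment grid described by ``plan``.

    Per data set, tau is estimated once from that data set and shared by
    its bnggm chains; every chain seed derives deterministically from
    ``plan.master_seed``.  When ``plan.out_dir`` is set, traces are written
    as ``trace_d{dataset}_{mode}_c{chain}.npz`` and reused on re-runs if
    already present and loadable (cheap resume), alongside TSV summaries
    and a YAML manifest.
    """
    true_dag = plan.true_dag or benchmark_dag()
    root = np.random.SeedSequence(plan.master_seed)
    data_ss, chain_ss = root.spawn(2)
    data_seeds = [_chain_seed(s) for s in data_ss.spawn(plan.n_datasets)]
    datasets = _load_datasets(plan, data_seeds)

    out_dir = Path(plan.out_dir) if plan.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    traces: dict[tuple[int, str, int], ChainTrace] = {}
    manifest_runs = []
    chain_groups = chain_ss.spawn(plan.n_datasets * len(MODES) * plan.chains_per_dataset)
    gi = 0
    for d, dataset in enumerate(datasets):
        tau = compute_tau(dataset)
        for mode in MODES:
            for c in range(plan.chains_per_dataset):
                seed = _chain_seed(chain_groups[gi])
                gi += 1
                cfg = replace(plan.sampler, mode=mode, seed=seed)
                path = out_dir / f"trace_d{d}_{mode}_c{c}.npz" if out_dir else None
                trace = None
                if path is not None and path.exists():
                    try:
                        trace = ChainTrace.load(path)
                    except Exception:
                        trace = None  # corrupted trace: re-run this cell only
                if trace is None:
                    # paired chains differ by their seed (independent RNG
                    # initializations); both start from the empty graph
                    trace = run_chain(
                        dataset,
                        cfg,
                        tau=tau if mode == "bnggm" else None,
                        hyper=plan.hyper,
                    )
                    if path is not None:
                        trace.save(path)
                traces[(d, mode, c)] = trace
                manifest_runs.append(
                    {"dataset": d, "mode": mode, "chain": c, "seed": seed}
                )

    # accuracy: per data set, AUC trajectory averaged over chains, then
    # mean +/- sd across data sets per mode and step
    truth = true_dag.adjacency
    auc_rows, crms_rows = [], []
    for mode in MODES:
        per_ds_auc, per_ds_crms = [], []
        for d in range(plan.n_datasets):
            chains = [traces[(d, mode, c)] for c in range(plan.chains_per_dataset)]
            aucs = np.mean(
                [auc_trajectory(t, truth)["auc"].to_numpy() for t in chains], axis=0
            )
            per_ds_auc.append(aucs)
            per_ds_crms.append(
                crms_trajectory(chains[0], chains[1])["c_rms"].to_numpy()
            )
        steps = traces[(0, mode, 0)].steps
        per_ds_auc = np.asarray(per_ds_auc)
        per_ds_crms = np.asarray(per_ds_crms)
        auc_rows.append(
            pd.DataFrame(
                {
                    "mode": mode,
                    "step": steps,
                    "auc_mean": per_ds_auc.mean(axis=0),
                    "auc_sd": per_ds_auc.std(axis=0, ddof=1),
                }
            )
        )
        crms_rows.append(
            pd.DataFrame(
                {
                    "mode": mode,
                    "step": steps,
                    "c_rms_mean": per_ds_crms.mean(axis=0),
                    "c_rms_sd": per_ds_crms.std(axis=0, ddof=1),
                }
            )
        )
    auc_summary = pd.concat(auc_rows, ignore_index=True)
    crms_summary = pd.concat(crms_rows, ignore_index=True)

    manifest = {
        "master_seed": plan.master_seed,
        "data_type": plan.data_type,
        "n_datasets": plan.n_datasets,
        "chains_per_dataset": plan.chains_per_dataset,
        "data_seeds": data_seeds,
        "sim": vars(plan.sim),
        "sampler": {k: v for k, v in vars(plan.sampler).items()},
        "runs": manifest_runs,
    }
    if out_dir:
        auc_summary.to_csv(out_dir / "auc_summary.tsv", sep="\t", index=False)
        crms_summary.to_csv(out_dir / "crms_summary.tsv", sep="\t", index=False)
        with open(out_dir / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)
    return ExperimentResult(auc_summary, crms_summary, manifest, traces, true_dag)
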