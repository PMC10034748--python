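"""Seeded desk-scale experiment replicas.

Three scripted studies on synthetic data: the unroll-count study (including
the network-only arm), the spoke-budget sweep using one model trained at the
smallest budget, and the method comparison against the gridded and
L1-wavelet baselines. Every stage is driven by the spec's seeds so tables
regenerate bitwise.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .baselines import CSConfig, cg_sense, l1_wavelet_cs
from .blockwise import plan_blocks
from .forward_model import (
    EncodingOperator,
    gridded_recon,
    normalize_operator,
    rescale_kspace,
)
from .metrics import paired_t_test, relative_difference
from .model import RegularizerConfig, UnrolledModel
from .synthetic import (
    make_coil_maps,
    make_dcf,
    make_phantom,
    make_trajectory,
    simulate_acquisition,
    subsample_spokes,
)
from .training import TrainConfig, TrainingCase, train

__all__ = [
    "ExperimentSpec",
    "build_cases",
    "run_unroll_study",
    "run_spokes_sweep",
    "run_method_comparison",
]


@dataclass
class ExperimentSpec:
    """Fully serializable description of a synthetic experiment.

    The defaults are desk scale (minutes on one CPU); the paper-scale
    configuration (20 coils, 32-channel regularizer with 2 residual blocks,
    5 unrolls, 4000 iterations, 5000-spoke training subsets) is expressible
    through the same fields.
    """

    shape: tuple[int, int, int] = (32, 32, 32)
    n_coils: int = 4
    n_train_phantoms: int = 2
    n_test_phantoms: int = 5
    dense_spokes: int = 1500
    input_spokes: int = 250
    n_readout: int | None = None
    reg_channels: int = 8
    n_res_blocks: int = 1
    splits: tuple[int, int, int] = (2, 2, 2)
    unroll_list: tuple[int, ...] = (0, 1, 5)  # 0 = network-only arm
    mbdl_unrolls: int = 5
    train_iterations: int = 60
    learning_rate: float = 1e-3
    power_iters: int = 12
    power_tol: float = 1e-3
    spoke_budgets: tuple[int, ...] = (250, 375, 500, 750)
    cs_iters: int = 100
    cs_weight: float = 1e-4
    reference: str = "phantom"  # or "cgsense" (proxy protocol)
    cg_iters: int = 30
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self):
        self.shape = tuple(int(n) for n in self.shape)
        self.splits = tuple(int(n) for n in self.splits)
        self.unroll_list = tuple(int(u) for u in self.unroll_list)
        self.spoke_budgets = tuple(int(s) for s in self.spoke_budgets)
        if self.n_readout is None:
            self.n_readout = int(self.shape[0])
        if self.reference not in ("phantom", "cgsense"):
            raise ValueError(f"unknown reference mode {self.reference!r}")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentSpec":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def regularizer_config(self, init_seed=None) -> RegularizerConfig:
        return RegularizerConfig(
            channels=self.reg_channels,
            n_res_blocks=self.n_res_blocks,
            init_seed=self.seed if init_seed is None else init_seed,
        )

    def block_scheme(self):
        radius = self.regularizer_config().receptive_radius
        return plan_blocks(self.shape, self.splits, halo=radius)


@dataclass
class _Case:
    training: TrainingCase
    reference: np.ndarray
    case_seed: int


def _build_case(spec: ExperimentSpec, seed: int) -> _Case:
    phantom = make_phantom(spec.shape, seed=seed)
    maps = make_coil_maps(spec.shape, spec.n_coils, seed=seed + 1000)
    traj = make_trajectory(spec.dense_spokes, spec.n_readout,
                           grid_n=spec.shape[0])
    y = simulate_acquisition(phantom, maps, traj, noise_sigma=0.0)
    if spec.reference == "cgsense":
        op = EncodingOperator.from_components(maps, traj, make_dcf(traj))
        op = normalize_operator(op, n_iter=30, tol=1e-3)
        reference = cg_sense(rescale_kspace(op, y), op, n_iters=spec.cg_iters)
    else:
        reference = phantom.data
    return _Case(
        training=TrainingCase(gt_kspace=y, traj=traj, maps=maps,
                              target=reference),
        reference=reference,
        case_seed=seed,
    )


def build_cases(spec: ExperimentSpec):
    """Deterministic train/test case suites."""
    train_cases = [_build_case(spec, spec.seed + 100 + i)
                   for i in range(spec.n_train_phantoms)]
    test_cases = [_build_case(spec, spec.seed + 500 + i)
                  for i in range(spec.n_test_phantoms)]
    return train_cases, test_cases


def _test_problem(case: _Case, spec: ExperimentSpec, n_spokes: int):
    """Fixed-seed undersampled test input for a case (shared across arms)."""
    t = case.training
    y_sub, traj_sub, dcf_sub = subsample_spokes(
        t.gt_kspace, t.traj, n_spokes, seed=case.case_seed + 7
    )
    op = EncodingOperator.from_components(t.maps, traj_sub, dcf_sub)
    op = normalize_operator(op, n_iter=30, tol=1e-3)
    y_sub = rescale_kspace(op, y_sub)
    x_in = gridded_recon(op, y_sub)
    return x_in, y_sub, op


def _train_arm(spec: ExperimentSpec, train_cases, n_unrolls: int):
    network_only = n_unrolls == 0
    model = UnrolledModel(
        n_unrolls=0 if network_only else n_unrolls,
        config=spec.regularizer_config(),
        scheme=spec.block_scheme(),
        network_only=network_only,
    )
    cfg = TrainConfig(
        learning_rate=spec.learning_rate,
        n_iterations=spec.train_iterations,
        spokes_per_example=spec.input_spokes,
        seed=spec.seed,
        power_iters=spec.power_iters,
        power_tol=spec.power_tol,
    )
    _, trace = train(model, [c.training for c in train_cases], cfg)
    return model, trace


def _evaluate_model(model, test_cases, spec: ExperimentSpec,
                    n_spokes: int | None = None) -> pd.DataFrame:
    rows = []
    for i, case in enumerate(test_cases):
        x_in, y_sub, op = _test_problem(case, spec,
                                        n_spokes or spec.input_spokes)
        recon = model.forward(x_in, y_sub, op)
        m = relative_difference(recon, x_in, case.reference)
        rows.append({"case": i, **m.to_dict()})
    return pd.DataFrame(rows)


def _write_outputs(spec, name, table: pd.DataFrame, summary: dict):
    if spec.out_dir is None:
        return
    out = Path(spec.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / f"{name}.csv", index=False)
    (out / f"{name}.json").write_text(json.dumps(summary, indent=2))
    spec.to_yaml(out / f"{name}_spec.yaml")


def run_unroll_study(spec: ExperimentSpec) -> dict:
    """Train one model per unroll count (0 = network-only) with identical
    seeds and budgets; emit per-case relative-difference metrics and the
    paired test between the largest and smallest arms."""
    if len(spec.unroll_list) < 2:
        raise ValueError("need at least 2 unroll settings")
    train_cases, test_cases = build_cases(spec)
    tables, models, traces = [], {}, {}
    for u in spec.unroll_list:
        model, trace = _train_arm(spec, train_cases, u)
        df = _evaluate_model(model, test_cases, spec)
        df.insert(0, "unrolls", u)
        tables.append(df)
        models[u] = model
        traces[u] = trace
    table = pd.concat(tables, ignore_index=True)
    lo, hi = min(spec.unroll_list), max(spec.unroll_list)
    rel_lo = table[table.unrolls == lo]
    rel_hi = table[table.unrolls == hi]
    tt_psnr = paired_t_test(rel_hi.psnr_rel.values, rel_lo.psnr_rel.values)
    tt_ssim = paired_t_test(rel_hi.ssim_rel.values, rel_lo.ssim_rel.values)
    summary = {
        "mean_psnr_rel": {int(u): float(table[table.unrolls == u].psnr_rel.mean())
                          for u in spec.unroll_list},
        "mean_ssim_rel": {int(u): float(table[table.unrolls == u].ssim_rel.mean())
                          for u in spec.unroll_list},
        "paired_t": {
            "arms": [int(hi), int(lo)],
            "psnr_rel": {"t": tt_psnr.t, "p": tt_psnr.p},
            "ssim_rel": {"t": tt_ssim.t, "p": tt_ssim.p},
        },
    }
    _write_outputs(spec, "unroll_study", table, summary)
    return {"table": table, "summary": summary, "models": models,
            "loss_traces": traces}


def run_spokes_sweep(spec: ExperimentSpec, model: UnrolledModel | None = None) -> dict:
    """Evaluate ONE model (trained at the smallest budget) across spoke
    budgets without retraining."""
    train_cases, test_cases = build_cases(spec)
    if model is None:
        model, _ = _train_arm(spec, train_cases, spec.mbdl_unrolls)
    tables = []
    for n_spokes in spec.spoke_budgets:
        df = _evaluate_model(model, test_cases, spec, n_spokes=n_spokes)
        df.insert(0, "n_spokes", n_spokes)
        tables.append(df)
    table = pd.concat(tables, ignore_index=True)
    summary = {
        "mean_psnr": {int(n): float(table[table.n_spokes == n].psnr.mean())
                      for n in spec.spoke_budgets},
        "mean_ssim": {int(n): float(table[table.n_spokes == n].ssim.mean())
                      for n in spec.spoke_budgets},
    }
    _write_outputs(spec, "spokes_sweep", table, summary)
    return {"table": table, "summary": summary, "model": model}


def run_method_comparison(spec: ExperimentSpec,
                          model: UnrolledModel | None = None) -> dict:
    """Per-case metrics for gridded / L1-wavelet CS / unrolled model against
    the reference, plus paired t-tests on the relative differences."""
    train_cases, test_cases = build_cases(spec)
    if model is None:
        model, _ = _train_arm(spec, train_cases, spec.mbdl_unrolls)
    cs_cfg = CSConfig(reg_weight=spec.cs_weight, n_iters=spec.cs_iters)
    rows = []
    import time
    for i, case in enumerate(test_cases):
        x_in, y_sub, op = _test_problem(case, spec, spec.input_spokes)
        recons = {}
        times = {}
        t0 = time.perf_counter()
        recons["gridded"] = x_in
        times["gridded"] = time.perf_counter() - t0
        t0 = time.perf_counter()
        recons["l1_wavelet"] = l1_wavelet_cs(y_sub, op, cs_cfg)
        times["l1_wavelet"] = time.perf_counter() - t0
        t0 = time.perf_counter()
        recons["mbdl"] = model.forward(x_in, y_sub, op)
        times["mbdl"] = time.perf_counter() - t0
        for method, recon in recons.items():
            m = relative_difference(recon, x_in, case.reference)
            rows.append({"method": method, "case": i,
                         "walltime_s": times[method], **m.to_dict()})
    table = pd.DataFrame(rows)
    mb = table[table.method == "mbdl"].sort_values("case")
    cs = table[table.method == "l1_wavelet"].sort_values("case")
    tt_psnr = paired_t_test(mb.psnr_rel.values, cs.psnr_rel.values)
    tt_ssim = paired_t_test(mb.ssim_rel.values, cs.ssim_rel.values)
    summary = {
        "mean_psnr_rel": {m: float(table[table.method == m].psnr_rel.mean())
                          for m in recons},
        "mean_ssim_rel": {m: float(table[table.method == m].ssim_rel.mean())
                          for m in recons},
        "paired_t_mbdl_vs_cs": {
            "psnr_rel": {"t": tt_psnr.t, "p": tt_psnr.p},
            "ssim_rel": {"t": tt_ssim.t, "p": tt_ssim.p},
        },
    }
    _write_outputs(spec, "method_comparison", table, summary)
    return {"table": table, "summary": summary, "model": model}
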