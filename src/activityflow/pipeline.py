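"""End-to-end orchestration: simulate -> GLM -> FC -> mapping -> statistics.

Runs the full analysis on a synthetic dataset split into discovery and
replication halves that are analyzed identically but independently, and
writes TSV/JSON results plus a text summary comparing the halves.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np

from . import actflow, network, nulls, selectivity as sel
from .config import SimulationConfig
from .connectivity import combinedfc
from .glm import build_design, estimate_betas
from .io import write_json, write_matrix_tsv
from .synth import SyntheticDataset, simulate_dataset

log = logging.getLogger("activityflow.pipeline")


@dataclass
class PipelineConfig:
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    use_glm: bool = True
    fc_method: str = "combinedfc"  # or "truth"
    run_dominance: bool = True
    run_nulls: bool = True
    n_perm: int = 1000
    split_seed: int = 0
    out_dir: Optional[str] = None

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        if isinstance(sim, dict):
            if "category_conditions" in sim:
                sim["category_conditions"] = {
                    k: tuple(v) for k, v in sim["category_conditions"].items()
                }
            sim = SimulationConfig(**sim)
        return cls(sim=sim, **d)

    def config_hash(self) -> str:
        payload = json.dumps(
            {"sim": self.sim.to_dict(), "use_glm": self.use_glm,
             "fc_method": self.fc_method, "n_perm": self.n_perm,
             "split_seed": self.split_seed,
             "run_dominance": self.run_dominance,
             "run_nulls": self.run_nulls},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _betas(dataset: SyntheticDataset, participants, use_glm: bool):
    cfg = dataset.config
    if not use_glm or not dataset.task_bold:
        return [dataset.truth_activations[p] for p in participants]
    n_tp = dataset.task_bold[participants[0]].shape[1]
    design = build_design(dataset.design, n_timepoints=n_tp, dt=1.0)
    return [estimate_betas(dataset.task_bold[p], design) for p in participants]


def _fc_per_participant(dataset: SyntheticDataset, participants, method: str):
    if method == "truth":
        return [dataset.model.weights for _ in participants]
    if method != "combinedfc":
        raise ValueError(f"unknown fc_method {method!r}")
    return [
        combinedfc(dataset.rest_timeseries[p]).weights for p in participants
    ]


def analyze_half(dataset: SyntheticDataset, participants: List[int],
                 cfg: PipelineConfig) -> Dict:
    """Run all enabled stages on one half of the participants."""
    model, sim = dataset.model, dataset.config
    betas = _betas(dataset, participants, cfg.use_glm)
    fcs = _fc_per_participant(dataset, participants, cfg.fc_method)
    targets = model.target_units

    result: Dict = {"n_participants": len(participants)}
    sel_actual: Dict[str, list] = {}
    sel_mapped: Dict[str, list] = {}
    accs = []
    for act, fc in zip(betas, fcs):
        fmap = actflow.map_activity(act, fc, targets=targets)
        mapped_full = act.copy()
        mapped_full[targets] = fmap.mapped
        accs.append(
            actflow.accuracy(act[targets], fmap.mapped)
        )
        for name, cx in model.complexes.items():
            cat = cx["category"]
            a_sel, m_sel = sel.category_selectivity(
                act, mapped_full,
                sim.category_conditions[cat],
                sel.noncategory_conditions(sim.category_conditions, cat),
                units=cx["units"],
                unit_aggregation="average-then-ratio",
            )
            sel_actual.setdefault(name, []).append(a_sel)
            sel_mapped.setdefault(name, []).append(m_sel)

    result["accuracy"] = {
        "pearson_r": float(np.mean([a.pearson_r for a in accs])),
        "mae": float(np.mean([a.mae for a in accs])),
        "r_squared": float(np.mean([a.r_squared for a in accs])),
    }

    complexes = list(model.complexes)
    contribs = {}
    sel_table = {}
    for name in complexes:
        a = np.array(sel_actual[name])
        m = np.array(sel_mapped[name])
        pct = sel.distributed_contribution(m, a)
        _, flags = sel.remove_outliers(pct) if len(pct) >= 3 else (pct, np.zeros(len(pct), bool))
        contribs[name] = pct[~flags]
        sel_table[name] = {
            "actual_selectivity_mean": float(a[~flags].mean()),
            "mapped_selectivity_mean": float(m[~flags].mean()),
            "contribution_pct_mean": float(pct[~flags].mean()),
            "n_outliers": int(flags.sum()),
        }
    result["selectivity"] = sel_table

    if cfg.run_nulls and len(participants) >= 2:
        sel_m = np.column_stack([sel_mapped[n] for n in complexes])
        mt_sel = nulls.maxt_test(sel_m, null_mean=1.0, n_perm=cfg.n_perm,
                                 scheme="sign_flip", seed=sim.seed + 1)
        pct_m = np.column_stack(
            [sel.distributed_contribution(
                np.array(sel_mapped[n]), np.array(sel_actual[n])
            ) for n in complexes]
        )
        mt_pct = nulls.maxt_test(pct_m, null_mean=50.0, n_perm=cfg.n_perm,
                                 scheme="sign_flip", seed=sim.seed + 2)
        result["maxt"] = {
            "selectivity_vs_1": {
                n: {"t": float(t), "p_corrected": float(p)}
                for n, t, p in zip(complexes, mt_sel.observed_t,
                                   mt_sel.corrected_p)
            },
            "contribution_vs_50": {
                n: {"t": float(t), "p_corrected": float(p)}
                for n, t, p in zip(complexes, mt_pct.observed_t,
                                   mt_pct.corrected_p)
            },
            "n_perm": cfg.n_perm,
        }
        # fingerprint-substitution nulls: true mapped selectivity vs donors
        sub = {}
        for name in complexes:
            cat = model.complexes[name]["category"]
            donors = {}
            for donor in complexes:
                if donor == name:
                    continue
                null_sels = []
                for act, fc in zip(betas, fcs):
                    fc_null = nulls.substitute_fingerprint(
                        fc, model.complexes[name]["units"],
                        model.complexes[donor]["units"],
                    )
                    fmap = actflow.map_activity(
                        act, fc_null, targets=model.complexes[name]["units"]
                    )
                    mapped_full = act.copy()
                    mapped_full[model.complexes[name]["units"]] = fmap.mapped
                    _, m_sel = sel.category_selectivity(
                        act, mapped_full,
                        sim.category_conditions[cat],
                        sel.noncategory_conditions(sim.category_conditions, cat),
                        units=model.complexes[name]["units"],
                        unit_aggregation="average-then-ratio",
                    )
                    null_sels.append(m_sel)
                donors[donor] = {
                    "null_mapped_selectivity_mean": float(np.mean(null_sels)),
                    "true_minus_null_mean": float(
                        np.mean(np.array(sel_mapped[name]) - np.array(null_sels))
                    ),
                }
            sub[name] = donors
        result["substitution_nulls"] = sub

    if cfg.run_dominance:
        dom = {}
        for name, cx in model.complexes.items():
            partials = []
            fulls = []
            all_labels = list(dict.fromkeys(model.partition.tolist()))
            for act, fc in zip(betas, fcs):
                comps = network.network_restricted_maps(
                    act, fc, model.partition, targets=cx["units"]
                )
                profiles = {lab: comp.mean(axis=0) for lab, comp in comps.items()}
                # constant (e.g. all-zero) components carry no variance
                constant = [lab for lab, v in profiles.items() if np.ptp(v) == 0]
                for lab in constant:
                    del profiles[lab]
                actual_profile = act[cx["units"]].mean(axis=0)
                res = network.dominance(profiles, actual_profile)
                part = dict.fromkeys(all_labels, 0.0)
                part.update(res.partial_r2)
                partials.append(part)
                fulls.append(res.full_r2)
            if fulls:
                dom[name] = {
                    "full_r2_mean": float(np.mean(fulls)),
                    "partial_r2_mean": {
                        lab: float(np.mean([p[lab] for p in partials]))
                        for lab in all_labels
                    },
                }
        result["dominance"] = dom
    return result


def run_pipeline(cfg: PipelineConfig) -> Dict:
    """Simulate, split into halves, analyze each, and write the report."""
    t0 = time.time()
    log.info("simulating dataset (seed=%d)", cfg.sim.seed)
    dataset = simulate_dataset(cfg.sim, include_bold=cfg.use_glm)

    rng = np.random.default_rng([cfg.split_seed, cfg.sim.seed])
    order = rng.permutation(cfg.sim.n_participants)
    half = cfg.sim.n_participants // 2
    halves = {
        "discovery": sorted(int(i) for i in order[:half]),
        "replication": sorted(int(i) for i in order[half:]),
    }

    report: Dict = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.sim.seed,
        "split": halves,
        "halves": {},
    }
    for label, participants in halves.items():
        log.info("analyzing %s half (n=%d)", label, len(participants))
        report["halves"][label] = analyze_half(dataset, participants, cfg)
    log.info("pipeline finished in %.2fs", time.time() - t0)

    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_json(out / "report.json", report)
        write_matrix_tsv(out / "ground_truth_weights.tsv",
                         dataset.model.weights)
        (out / "summary.txt").write_text(_summary_text(report))
    return report


def _summary_text(report: Dict) -> str:
    lines = [
        f"activityflow pipeline report (config {report['config_hash']}, "
        f"seed {report['seed']})",
        "",
    ]
    halves = report["halves"]
    for name in next(iter(halves.values()))["selectivity"]:
        lines.append(f"complex {name}:")
        for label, res in halves.items():
            s = res["selectivity"][name]
            lines.append(
                f"  {label:<12} actual sel {s['actual_selectivity_mean']:.3f}  "
                f"mapped sel {s['mapped_selectivity_mean']:.3f}  "
                f"contribution {s['contribution_pct_mean']:.1f}%"
            )
        if len(halves) == 2:
            a, b = [halves[k]["selectivity"][name]["contribution_pct_mean"]
                    for k in halves]
            lines.append(f"  half agreement: contribution diff {abs(a - b):.2f} pts")
    for label, res in halves.items():
        acc = res["accuracy"]
        lines.append(
            f"{label}: mapping accuracy r={acc['pearson_r']:.3f} "
            f"MAE={acc['mae']:.3f} R2={acc['r_squared']:.3f}"
        )
    return "\n".join(lines) + "\n"
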