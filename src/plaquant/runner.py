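"""End-to-end orchestration: simulate → quantify → compare → CTF bounds.

One top-level seed deterministically derives all per-image seeds, so a run is
reproducible from a single number. Every run writes its resolved
configuration next to its outputs, plus per-image provenance (thresholds and
focus planes) in the results CSVs and the log.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field

import yaml

from .ctf import CtfInputs, decompose_cterm_signal, sensitivity_table
from .exceptions import ParameterError, PlaquantError
from .io import write_results_table
from .organelle import OrganelleParams, quantify_organelle_image
from .pla import PlaParams, quantify_pla_image
from .stats import MeasurementSample, fold_change_vs_calibrator, rout_outliers, t_test_two_tailed
from .synthetic import SceneSpec, generate_group_experiment

log = logging.getLogger("plaquant")

#: Demo-scale scene geometry: small enough for a laptop-minutes run while
#: keeping the sparse-bright-dots-on-dark-background thresholding regime.
_DEMO_SHAPE = (12, 128, 128)


@dataclass
class RunConfig:
    """Resolved configuration of one end-to-end run."""

    out_dir: str = "plaq-run"
    seed: int = 0
    n_images_per_group: int = 8
    group_labels: tuple[str, str] = ("NPC", "neuron")
    # PLA comparison: dot counts per group (neurons: +63 % flAPP/BACE1 signal)
    pla_dots_low: int = 60
    pla_dots_high: int = 98
    # organelle comparison: fraction of dots placed inside organelles
    organelle_fraction_low: float = 0.5
    organelle_fraction_high: float = 0.2
    organelle_kind: str = "Rab5a"
    shape: tuple[int, int, int] = _DEMO_SHAPE
    rout_q: float = 0.001
    r_flapp: float = 1.63
    r_cterm: float = 0.21
    log_level: str = "INFO"
    scene_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_images_per_group < 2:
            raise ParameterError("n_images_per_group must be >= 2")
        self.shape = tuple(self.shape)
        self.group_labels = tuple(self.group_labels)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _scene(config: RunConfig, **kwargs) -> SceneSpec:
    base = dict(shape=config.shape, n_nuclei=1,
                nucleus_radii=(8.0, 30.0, 30.0), n_organelles=25,
                organelle_radius=6.0)
    base.update(config.scene_overrides)
    base.update(kwargs)
    return SceneSpec(**base)


def run_end_to_end(config: RunConfig) -> str:
    """Run the whole synthetic NPC-vs-neuron comparison; returns the out dir."""
    os.makedirs(config.out_dir, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    config.to_yaml(os.path.join(config.out_dir, "config.resolved.yaml"))

    report: list[str] = []

    # --- PLA (macro 1) -----------------------------------------------------
    low = _scene(config, n_pla_dots=config.pla_dots_low, primary="nucleus")
    high = _scene(config, n_pla_dots=config.pla_dots_high, primary="nucleus")
    manifest, pairs, _ = generate_group_experiment(
        low, high, config.n_images_per_group, base_seed=config.seed,
        out_dir=os.path.join(config.out_dir, "pla_images"),
        group_labels=config.group_labels)
    pla_results = []
    for pair in pairs:
        try:
            res = quantify_pla_image(pair, PlaParams())
        except PlaquantError as exc:
            log.warning("stage=pla image=%s excluded: %s", pair.image_id, exc)
            continue
        log.info("stage=pla image=%s focus=(%d,%d) thresholds=(%.3f,%.3f) ratio=%.5f",
                 res.image_id, res.best_focus_nucleus, res.best_focus_pla,
                 res.band_nucleus.lower, res.band_pla.lower, res.ratio)
        pla_results.append(res)
    write_results_table(pla_results, os.path.join(config.out_dir, "pla_results.csv"))

    report.append("== pla ==")
    report.append(f"images quantified: {len(pla_results)} "
                  f"(of {2 * config.n_images_per_group})")

    # --- group statistics on the PLA ratios --------------------------------
    la, lb = config.group_labels
    ratios = {g: [r.ratio for r in pla_results if r.group_label == g]
              for g in (la, lb)}
    rout_a = rout_outliers(MeasurementSample(ratios[la], la), q=config.rout_q)
    rout_b = rout_outliers(MeasurementSample(ratios[lb], lb), q=config.rout_q)
    comparison = t_test_two_tailed(rout_a.kept, rout_b.kept)
    folds = fold_change_vs_calibrator(rout_a.kept, rout_b.kept)

    report.append("== stats ==")
    report.append(f"ROUT (Q={config.rout_q:g}): removed "
                  f"{rout_a.n_outliers} of {len(ratios[la])} ({la}), "
                  f"{rout_b.n_outliers} of {len(ratios[lb])} ({lb})")
    report.append(f"{la}: mean={comparison.mean_a:.5f} sem={comparison.sem_a:.5f} "
                  f"n={comparison.n_a}")
    report.append(f"{lb}: mean={comparison.mean_b:.5f} sem={comparison.sem_b:.5f} "
                  f"n={comparison.n_b}")
    report.append(f"fold change {lb} vs {la} (calibrator=1): "
                  f"{folds.mean_fold_other_vs_calibrator:.4f}")
    report.append(f"t={comparison.t_statistic:.4f} df={comparison.df} "
                  f"p={comparison.p_value:.3g} "
                  f"significant={comparison.significant}")

    # --- organelle occupancy (macro 2) --------------------------------------
    org_low = _scene(config, n_pla_dots=config.pla_dots_low, primary="organelle",
                     fraction_dots_in_organelle=config.organelle_fraction_low)
    org_high = _scene(config, n_pla_dots=config.pla_dots_low, primary="organelle",
                      fraction_dots_in_organelle=config.organelle_fraction_high)
    _, org_pairs, _ = generate_group_experiment(
        org_low, org_high, config.n_images_per_group,
        base_seed=config.seed + 1,
        out_dir=os.path.join(config.out_dir, "organelle_images"),
        group_labels=config.group_labels, organelle_kind=config.organelle_kind)
    org_results = []
    for pair in org_pairs:
        try:
            res = quantify_organelle_image(pair, OrganelleParams())
        except PlaquantError as exc:
            log.warning("stage=organelle image=%s excluded: %s", pair.image_id, exc)
            continue
        log.info("stage=organelle image=%s focus=(%d,%d) percent=%.3f",
                 res.image_id, res.best_focus_organelle, res.best_focus_pla,
                 res.percent_occupied)
        org_results.append(res)
    write_results_table(org_results,
                        os.path.join(config.out_dir, "organelle_results.csv"))

    org_pcts = {g: [r.percent_occupied for r in org_results if r.group_label == g]
                for g in (la, lb)}
    org_cmp = t_test_two_tailed(MeasurementSample(org_pcts[la], la),
                                MeasurementSample(org_pcts[lb], lb))
    report.append("== organelle ==")
    report.append(f"{config.organelle_kind} occupancy, {la}: "
                  f"mean={org_cmp.mean_a:.3f}% sem={org_cmp.sem_a:.3f} n={org_cmp.n_a}")
    report.append(f"{config.organelle_kind} occupancy, {lb}: "
                  f"mean={org_cmp.mean_b:.3f}% sem={org_cmp.sem_b:.3f} n={org_cmp.n_b}")
    report.append(f"t={org_cmp.t_statistic:.4f} df={org_cmp.df} "
                  f"p={org_cmp.p_value:.3g}")

    # --- CTF decomposition ---------------------------------------------------
    inputs = CtfInputs(r_flapp=config.r_flapp, r_cterm=config.r_cterm)
    bounds = decompose_cterm_signal(inputs)
    scan = sensitivity_table(inputs, [round(0.18 + 0.01 * i, 2) for i in range(8)])
    scan.to_csv(os.path.join(config.out_dir, "ctf_sensitivity.csv"), index=False)
    report.append("== ctf ==")
    report.append(f"inputs: r_flapp={inputs.r_flapp} r_cterm={inputs.r_cterm}")
    report.append(f"min NPC:neuron CTF ratio >= "
                  f"{bounds.min_npc_to_neuron_ctf_ratio:.3f}")
    report.append(f"min NPC CTF:flAPP ratio >= {bounds.min_ctf_to_flapp_npc:.3f}")

    report_path = os.path.join(config.out_dir, "report.txt")
    with open(report_path, "w") as fh:
        fh.write("\n".join(report) + "\n")
    log.info("report written to %s", report_path)
    return config.out_dir
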