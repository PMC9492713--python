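"""Configuration-driven orchestration of the full brain-state analysis.

Stages: simulate -> align signs -> embed/PCA + HMM fit -> spectra ->
temporal metrics -> group statistics -> report.  Every stage writes a
checkpoint artifact into the output directory and records its content hash
in a run manifest, so re-running with an identical configuration reuses
(and verifies) existing artifacts, and a single global seed makes the whole
chain reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import save_cohort_hdf5, load_cohort_hdf5
from .embedding import EmbeddingConfig, align_signs
from .hmm import HmmConfig, TimeDelayEmbeddedHMM
from .metrics import cohort_temporal_metrics
from .simulate import default_cohort_spec, simulate_cohort, corrupt_signs, \
    GroupEffect
from .spectral import MultitaperConfig, nnmf_frequency_modes, \
    collapse_to_bands
from .stats import band_power_group_tests

log = logging.getLogger("tdehmm")

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "report"]


@dataclass
class SimulateConfig:
    n_per_group: int = 2
    n_channels: int = 12
    fs: float = 250.0
    duration: float = 60.0
    persistence: float = 0.98
    frequencies: tuple = (5.0, 10.0, 20.0, 35.0)
    noise_sd: float = 0.2
    subject_amp_sd: float = 0.15
    flip_prob: float = 0.0
    power_effect: dict | None = None   # {"state_id":, "channels":, "multiplier":}


@dataclass
class StatsConfig:
    n_perm: int = 5000
    n_boot: int = 2000
    q: float = 0.05
    exclude_gamma: bool = True
    n_modes: int = 4
    nnmf_restarts: int = 20


@dataclass
class PipelineConfig:
    output_dir: str = "tdehmm_run"
    seed: int = 0
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    embedding: EmbeddingConfig = field(default_factory=EmbeddingConfig)
    hmm: HmmConfig = field(default_factory=lambda: HmmConfig(
        K=4, n_runs=3, max_iterations=40))
    multitaper: MultitaperConfig = field(default_factory=MultitaperConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) \
            else json.loads(text)
        cfg = cls()
        for key, sub in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config section {key!r}")
            cur = getattr(cfg, key)
            if dataclasses.is_dataclass(cur) and isinstance(sub, dict):
                for k, v in sub.items():
                    if not hasattr(cur, k):
                        raise ValueError(f"unknown option {key}.{k}")
                    setattr(cur, k, v)
            else:
                setattr(cfg, key, sub)
        cfg.hmm.__post_init__()
        cfg.embedding.__post_init__()
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)

        def clean(x):
            if isinstance(x, dict):
                return {k: clean(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [clean(v) for v in x]
            if isinstance(x, np.generic):
                return x.item()
            return x
        return clean(d)


@dataclass
class RunManifest:
    config: dict
    stages: dict = field(default_factory=dict)   # name -> {file, sha256, t}
    version: str = ""

    def record(self, stage: str, path: Path) -> None:
        h = hashlib.sha256(path.read_bytes()).hexdigest()
        self.stages[stage] = {"file": path.name, "sha256": h,
                              "timestamp": time.time()}

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(
            {"config": self.config, "stages": self.stages,
             "version": self.version}, indent=2, default=str))


def _seed_for(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2 ** 31)


def run_pipeline(config: PipelineConfig, resume: bool = True):
    """Execute the full chain; returns ``(manifest, outputs)`` where
    ``outputs`` maps stage names to in-memory results."""
    from . import __version__
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), version=__version__)
    outputs = {}
    t0 = time.time()

    # --- simulate ---------------------------------------------------------
    sim = config.simulate
    effects = []
    if sim.power_effect:
        effects.append(GroupEffect(target="power",
                                   state_id=sim.power_effect["state_id"],
                                   channels=tuple(
                                       sim.power_effect["channels"]),
                                   multiplier=sim.power_effect["multiplier"]))
    spec = default_cohort_spec(
        n_per_group=sim.n_per_group, n_channels=sim.n_channels, fs=sim.fs,
        duration=sim.duration, persistence=sim.persistence,
        frequencies=tuple(sim.frequencies), noise_sd=sim.noise_sd,
        subject_amp_sd=sim.subject_amp_sd, group_effects=effects,
        seed=_seed_for(config.seed, "simulate"))
    cohort_path = out / "cohort.h5"
    if resume and cohort_path.exists():
        subjects, gt = load_cohort_hdf5(cohort_path)
        log.info("simulate: reusing %s", cohort_path)
    else:
        subjects, gt = simulate_cohort(spec)
        if sim.flip_prob > 0:
            subjects, applied = corrupt_signs(
                subjects, sim.flip_prob, _seed_for(config.seed, "flips"))
            gt.applied_flips = applied
        save_cohort_hdf5(cohort_path, subjects, gt, spec.to_json())
    manifest.record("simulate", cohort_path)
    outputs["subjects"], outputs["ground_truth"] = subjects, gt
    log.info("simulate done (%.1fs)", time.time() - t0)

    # --- sign alignment ----------------------------------------------------
    aligned, flips, score = align_signs(subjects)
    outputs["flips"] = flips
    log.info("align done, score %.3f (%.1fs)", score, time.time() - t0)

    # --- embed + fit --------------------------------------------------------
    hmm_cfg = dataclasses.replace(
        config.hmm, seed=_seed_for(config.seed, "hmm"))
    model = TimeDelayEmbeddedHMM(aligned, embedding=config.embedding,
                                 config=hmm_cfg)
    res = model.fit()
    fit_path = out / "hmm_fit.h5"
    res.save(fit_path)
    manifest.record("fit", fit_path)
    outputs["results"] = res
    log.info("fit done, F=%.1f (%.1fs)", res.free_energy, time.time() - t0)

    # --- spectra ------------------------------------------------------------
    spectra = res.state_spectra(config.multitaper)
    modes = nnmf_frequency_modes(
        spectra, n_modes=config.stats.n_modes,
        n_restarts=config.stats.nnmf_restarts,
        seed=_seed_for(config.seed, "nnmf"))
    band_power, band_coh = collapse_to_bands(spectra, modes)
    outputs["spectra"], outputs["modes"] = spectra, modes
    outputs["band_power"], outputs["band_coherence"] = band_power, band_coh
    bp_path = out / "band_power.csv"
    _band_power_csv(bp_path, band_power, spectra, modes)
    manifest.record("spectra", bp_path)
    log.info("spectra done (%.1fs)", time.time() - t0)

    # --- temporal metrics ---------------------------------------------------
    tm = res.temporal_metrics()
    tm_path = out / "temporal_metrics.csv"
    tm.to_dataframe().to_csv(tm_path, index=False)
    manifest.record("metrics", tm_path)
    outputs["temporal_metrics"] = tm
    log.info("metrics done (%.1fs)", time.time() - t0)

    # --- statistics ---------------------------------------------------------
    groups = np.asarray([s.group for s in subjects])
    stats_df = None
    if len(set(groups)) == 2 and min(
            (groups == g).sum() for g in set(groups)) >= 2:
        scalar = np.nanmean(band_power, axis=3)   # subj x K x modes
        stats_df = band_power_group_tests(
            scalar, groups, modes.labels, n_perm=config.stats.n_perm,
            seed=_seed_for(config.seed, "stats"), q=config.stats.q,
            exclude_gamma=config.stats.exclude_gamma,
            n_boot=config.stats.n_boot)
        st_path = out / "group_stats.csv"
        stats_df.to_csv(st_path, index=False)
        manifest.record("stats", st_path)
    outputs["group_stats"] = stats_df
    manifest.save(out / "manifest.json")
    log.info("pipeline done (%.1fs)", time.time() - t0)
    return manifest, outputs


def _band_power_csv(path, band_power, spectra, modes):
    S, K, M, C = band_power.shape
    s, k, m, c = np.meshgrid(np.arange(S), np.arange(K), np.arange(M),
                             np.arange(C), indexing="ij")
    pd.DataFrame({
        "subject": np.asarray(spectra.subject_ids)[s.ravel()],
        "group": np.asarray([g or "" for g in spectra.groups])[s.ravel()],
        "state": k.ravel() + 1,
        "band": np.asarray(modes.labels)[m.ravel()],
        "channel": c.ravel(),
        "power": band_power.ravel(),
    }).to_csv(path, index=False)


def report(output_dir: str | Path, outputs: dict | None = None,
           make_figures: bool = True) -> Path:
    """Write a static summary report (markdown + figures) from pipeline
    outputs.  Missing stages are listed and a partial report is produced."""
    out = Path(output_dir)
    lines = ["# Brain-state analysis report", ""]
    missing = []

    tm_path = out / "temporal_metrics.csv"
    if tm_path.exists():
        tm = pd.read_csv(tm_path)
        fo = tm[tm.metric == "fractional_occupancy"]
        lines += ["## Temporal features", "",
                  fo.groupby("state")["value"].agg(
                      ["mean", "std"]).round(4).to_markdown(), ""]
        sw = tm[tm.metric == "switching_rate"]
        lines += [f"Mean switching rate: "
                  f"{sw['value'].mean():.2f} switches/s", ""]
    else:
        missing.append("temporal_metrics")

    bp_path = out / "band_power.csv"
    if bp_path.exists():
        bp = pd.read_csv(bp_path)
        tab = bp.groupby(["state", "band"])["power"].mean().unstack()
        lines += ["## State band power (mean over subjects/channels)", "",
                  tab.round(5).to_markdown(), ""]
    else:
        missing.append("band_power")

    st_path = out / "group_stats.csv"
    if st_path.exists():
        st = pd.read_csv(st_path)
        lines += ["## Group differences (BH-FDR at 0.05)", "",
                  st.round(4).to_markdown(index=False), ""]
        sig = st[st.significant_fdr]
        if len(sig):
            for _, r in sig.iterrows():
                lines.append(f"* state {int(r.state)} / {r.band}: "
                             f"d = {r.d:.3f}, p = {r.p:.4f}")
        else:
            lines.append("No significant group differences.")
        lines.append("")
    else:
        missing.append("group_stats (descriptive report only)")

    if missing:
        lines += ["## Missing stages", ""] + [f"* {m}" for m in missing]

    if make_figures and outputs is not None and "spectra" in outputs:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        spectra = outputs["spectra"]
        mean_psd = np.nanmean(spectra.psd, axis=(0, 3))   # K x F
        fig, ax = plt.subplots(figsize=(6, 4))
        for k in range(mean_psd.shape[0]):
            ax.plot(spectra.frequencies, mean_psd[k], label=f"state {k+1}")
        ax.set_xlabel("frequency (Hz)")
        ax.set_ylabel("power (a.u.$^2$/Hz)")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out / "state_spectra.png", dpi=120)
        plt.close(fig)
        lines += ["", "![state spectra](state_spectra.png)"]

    path = out / "report.md"
    path.write_text("\n".join(lines))
    return path
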