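"""Pipeline orchestration: simulate -> de -> integrate -> baseline -> compare
-> enrich -> report, with a machine-readable run manifest.

A single YAML config governs every threshold (significance level, minimum
term size, minimum baseline TPM, mode ratio threshold, exceedance
threshold); each is echoed into the manifest so reports carry no hidden
defaults. Every stage output file is hashed (sha256) into the manifest;
re-running with the same config and seed reproduces identical hashes.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .abundance import mean_tpm, tpm
from .cross_species import (
    classify_all_modes,
    pairwise_log2_ratios,
    select_baseline_groups,
)
from .de_stats import summarize_deg_counts, wald_de_test, write_de_table, read_de_table
from .enrichment import fisher_ora
from .homology_integration import (
    assign_profiles,
    integrate_de_status,
    profile_census,
    response_score_matrix,
    select_species_specific_sets,
)
from .io_formats import (
    read_count_matrix,
    read_homology_table,
    read_sample_table,
    read_term_map,
)
from .synthetic import SimConfig, write_fixture

__all__ = ["RunManifest", "run_pipeline", "report", "ALL_STAGES", "default_config"]

ALL_STAGES = ["simulate", "de", "integrate", "baseline", "compare", "enrich", "report"]


def default_config() -> dict:
    return {
        "seed": 17,
        "out_dir": "results/pipeline",
        "reference_species": "At",
        "sim": {},
        "de": {"alpha_sig": 0.05, "min_basemean_quantile": 0.10},
        "baseline": {"min_tpm": 1.0, "exceedance_threshold": 0.0},
        "modes": {"ratio_t": 1.0, "pseudo": 0.01},
        "enrichment": {"min_term_size": 5},
    }


@dataclass
class RunManifest:
    """Record of a pipeline run: stages, output hashes, config, seed."""

    config: dict
    seed: int
    version: str = __version__
    started: str = ""
    finished: str = ""
    stages: List[dict] = field(default_factory=list)

    def add_stage(self, name: str, outputs: Mapping[str, str]) -> None:
        hashed = {}
        for label, path in outputs.items():
            digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
            hashed[label] = {"path": str(path), "sha256": digest}
        self.stages.append(
            {
                "name": name,
                "timestamp": _dt.datetime.now().isoformat(timespec="seconds"),
                "outputs": hashed,
            }
        )

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "seed": self.seed,
            "started": self.started,
            "finished": self.finished,
            "config": self.config,
            "stages": self.stages,
        }

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=str)


def _load_config(config) -> dict:
    cfg = default_config()
    if config is None:
        return cfg
    if isinstance(config, (str, Path)):
        with open(config, encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(config)
    for key, val in user.items():
        if isinstance(val, Mapping) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def run_pipeline(
    config=None,
    stages: Optional[Sequence[str]] = None,
    manifest_path=None,
) -> RunManifest:
    """Run the configured stage sequence; returns the populated manifest.

    Any stage failure aborts with the stage name in the error message.
    ``stages`` restricts execution (later stages read earlier stages'
    outputs from ``out_dir``).
    """
    cfg = _load_config(config)
    seed = int(cfg.get("seed", 17))
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    fixture_dir = out / "fixture"
    stages = list(stages) if stages is not None else list(ALL_STAGES)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}")

    manifest = RunManifest(config=cfg, seed=seed)
    manifest.started = _dt.datetime.now().isoformat(timespec="seconds")

    state: Dict[str, object] = {}

    def _load_inputs():
        sim_cfg = SimConfig.from_dict({**cfg.get("sim", {}), "seed": seed})
        samples = read_sample_table(fixture_dir / "samples.tsv", for_de=True)
        mats = {
            sp: read_count_matrix(
                fixture_dir / f"counts_{sp}.tsv",
                fixture_dir / f"lengths_{sp}.tsv",
                species_id=sp,
            )
            for sp in sim_cfg.species
        }
        homology = read_homology_table(fixture_dir / "homology.tsv")
        return sim_cfg, samples, mats, homology

    def stage_simulate():
        sim_cfg = SimConfig.from_dict({**cfg.get("sim", {}), "seed": seed})
        res = write_fixture(fixture_dir, sim_cfg, force=True)
        return {k: v for k, v in res["paths"].items()}

    def stage_de():
        sim_cfg, samples, mats, _ = _load_inputs()
        outputs = {}
        de = {}
        for sp, cm in mats.items():
            de[sp] = wald_de_test(
                cm,
                samples,
                alpha_sig=cfg["de"]["alpha_sig"],
                min_basemean_quantile=cfg["de"]["min_basemean_quantile"],
            )
            path = out / f"de_{sp}.tsv"
            write_de_table(de[sp], path)
            outputs[f"de_{sp}"] = str(path)
        state["de"] = de
        summary = summarize_deg_counts(de)
        path = out / "deg_summary.tsv"
        summary.to_csv(path, sep="\t")
        outputs["deg_summary"] = str(path)
        return outputs

    def _get_de(sim_cfg):
        if "de" not in state:
            state["de"] = {
                sp: read_de_table(out / f"de_{sp}.tsv") for sp in sim_cfg.species
            }
        return state["de"]

    def stage_integrate():
        sim_cfg, samples, mats, homology = _load_inputs()
        de = _get_de(sim_cfg)
        cls = integrate_de_status(homology, de, sim_cfg.species)
        nonamb = cls[
            (cls["membership"] == "core")
            & (cls["de_status"] == "DE")
            & (cls["ambiguity"] == "non_ambiguous")
        ]
        scores = response_score_matrix(nonamb, sim_cfg.species)
        profiles = assign_profiles(scores)
        cls = cls.join(profiles)
        cls["profile"] = cls["profile"].fillna("null")
        for sp in sim_cfg.species:
            cls[f"score_{sp}"] = scores[sp].reindex(cls.index)
        outputs = {}
        path = out / "hg_classification.tsv"
        cls.to_csv(path, sep="\t")
        outputs["classification"] = str(path)
        crosstab = pd.crosstab(cls["membership"], cls["de_status"], margins=True)
        path = out / "hg_crosstab.tsv"
        crosstab.to_csv(path, sep="\t")
        outputs["crosstab"] = str(path)
        census = profile_census(profiles)
        path = out / "profile_census.tsv"
        census.rename_axis("profile").to_frame().to_csv(path, sep="\t")
        outputs["census"] = str(path)
        state["cls"] = cls
        state["scores"] = scores
        return outputs

    def _get_cls():
        if "cls" not in state:
            cls = pd.read_csv(out / "hg_classification.tsv", sep="\t", index_col=0)
            state["cls"] = cls
        return state["cls"]

    def _abundances(sim_cfg, samples, mats):
        if "tpm" not in state:
            state["tpm"] = {sp: tpm(cm) for sp, cm in mats.items()}
            state["mean_tpm"] = {
                sp: mean_tpm(state["tpm"][sp], samples, "species")
                for sp in state["tpm"]
            }
        return state["tpm"], state["mean_tpm"]

    def stage_baseline():
        sim_cfg, samples, mats, homology = _load_inputs()
        cls = _get_cls()
        _, mean_sp = _abundances(sim_cfg, samples, mats)
        groups = select_baseline_groups(
            cls, homology, mean_sp, min_tpm=cfg["baseline"]["min_tpm"]
        )
        model = pairwise_log2_ratios(groups, homology, mean_sp)
        state["baseline"] = model
        threshold = cfg["baseline"]["exceedance_threshold"]
        path = out / "baseline_report.tsv"
        model.summary(threshold).to_csv(path, sep="\t", index=False)
        path2 = out / "baseline_offsets.tsv"
        model.species_offsets().rename_axis("species_id").to_frame().to_csv(
            path2, sep="\t"
        )
        return {"baseline_report": str(path), "baseline_offsets": str(path2)}

    def stage_compare():
        sim_cfg, samples, mats, homology = _load_inputs()
        de = _get_de(sim_cfg)
        cls = _get_cls()
        tpms, mean_sp = _abundances(sim_cfg, samples, mats)
        if "baseline" not in state:
            groups = select_baseline_groups(
                cls, homology, mean_sp, min_tpm=cfg["baseline"]["min_tpm"]
            )
            state["baseline"] = pairwise_log2_ratios(groups, homology, mean_sp)
        focal = sim_cfg.focal_species
        core = cls.index[
            (cls["membership"] == "core") & (cls[f"n_total_{focal}"] >= 1)
        ]
        modes = classify_all_modes(
            list(core),
            focal,
            de,
            state["baseline"],
            homology,
            tpms,
            samples,
            ratio_t=cfg["modes"]["ratio_t"],
            pseudo=cfg["modes"]["pseudo"],
        )
        state["modes"] = modes
        path = out / "mode_calls.tsv"
        modes.to_csv(path, sep="\t")
        return {"mode_calls": str(path)}

    def stage_enrich():
        sim_cfg, samples, mats, homology = _load_inputs()
        de = _get_de(sim_cfg)
        cls = _get_cls()
        ref = cfg.get("reference_species", "At")
        nonamb = cls[
            (cls["membership"] == "core")
            & (cls["de_status"] == "DE")
            & (cls["ambiguity"] == "non_ambiguous")
        ]
        scores = nonamb[[f"score_{sp}" for sp in sim_cfg.species]].rename(
            columns={f"score_{sp}": sp for sp in sim_cfg.species}
        )
        focal = sim_cfg.focal_species
        study = select_species_specific_sets(
            nonamb, scores, homology, "up", [focal], reference_species=ref
        )
        universe = set(de[ref].index[de[ref]["padj"].notna()])
        terms = read_term_map(fixture_dir / "terms.tsv")
        result = fisher_ora(
            study, universe, terms, min_term_size=cfg["enrichment"]["min_term_size"]
        )
        path = out / f"enrichment_{focal}_up.tsv"
        result.to_csv(path, sep="\t", index=False)
        return {"enrichment": str(path)}

    def stage_report():
        text = report_from_outputs(out, cfg)
        path = out / "report.md"
        path.write_text(text, encoding="utf-8")
        return {"report": str(path)}

    runners = {
        "simulate": stage_simulate,
        "de": stage_de,
        "integrate": stage_integrate,
        "baseline": stage_baseline,
        "compare": stage_compare,
        "enrich": stage_enrich,
        "report": stage_report,
    }
    for name in ALL_STAGES:
        if name not in stages:
            continue
        try:
            outputs = runners[name]()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        manifest.add_stage(name, outputs)
    manifest.finished = _dt.datetime.now().isoformat(timespec="seconds")
    if manifest_path is None:
        manifest_path = out / "manifest.json"
    manifest.save(manifest_path)
    return manifest


def report_from_outputs(out_dir, cfg) -> str:
    """Render the stage outputs as a markdown summary."""
    out = Path(out_dir)
    lines = ["# Cross-species light-response pipeline report", ""]
    lines.append("## Thresholds")
    for section in ("de", "baseline", "modes", "enrichment"):
        lines.append(f"- {section}: {cfg.get(section, {})}")
    lines.append("")

    def table(path, title):
        if not (out / path).exists():
            return
        df = pd.read_csv(out / path, sep="\t")
        lines.append(f"## {title}")
        lines.append(df.to_markdown(index=False))
        lines.append("")

    summary_path = out / "deg_summary.tsv"
    if summary_path.exists():
        df = pd.read_csv(summary_path, sep="\t")
        lines.append("## Differentially expressed genes per species")
        for _, row in df.iterrows():
            lines.append(
                f"- {row['species_id']}: {int(row['n_up']):,} up / "
                f"{int(row['n_down']):,} down / {int(row['n_unchanged']):,} unchanged "
                f"({row['pct_up']:.1f}% / {row['pct_down']:.1f}% / "
                f"{row['pct_unchanged']:.1f}%)"
            )
        lines.append("")
    table("hg_crosstab.tsv", "Homology groups by membership and DE status")
    table("profile_census.tsv", "Expression-profile census (non-ambiguous core DE)")
    table("baseline_report.tsv", "Transcriptional baseline (pairwise)")
    modes_path = out / "mode_calls.tsv"
    if modes_path.exists():
        df = pd.read_csv(modes_path, sep="\t")
        called = df[df["mode"] != "none"]
        lines.append("## Expression-mode calls (focal species)")
        if called.empty:
            lines.append("none detected")
        else:
            lines.append(called["mode"].value_counts().to_frame("n").to_markdown())
        lines.append("")
    enr = sorted(out.glob("enrichment_*.tsv"))
    for path in enr:
        df = pd.read_csv(path, sep="\t").head(10)
        lines.append(f"## Top enrichment results ({path.stem})")
        lines.append(df.to_markdown(index=False))
        lines.append("")
    return "\n".join(lines)


def report(manifest: RunManifest) -> str:
    """Human-readable summary of a completed run."""
    return report_from_outputs(Path(manifest.config["out_dir"]), manifest.config)
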