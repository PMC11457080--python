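"""Seeded multi-species RNA-seq simulator with planted ground truth.

The generator emulates the statistical structure the analysis assumes: four
species, two irradiance treatments (HL/LL) with five replicates each,
negative-binomial counts (variance ``mu + alpha*mu**2``), a homology table
with core / accessory / unique membership classes, lineage-specific paralog
expansions in a focal species, planted treatment effects, per-species
transcriptional-baseline offsets, and planted examples of the three
expression modes (treatment-dependent DE, constitutive single-copy
over-expression, cumulative paralog over-expression).

Baseline offsets are planted as transcriptome-composition differences: the
species-private (accessory + unique) background mass is rescaled so that
core-gene TPM values of species *a* sit ``offset_a - offset_b`` log2 units
above species *b* for genes of equal underlying expression. A uniform
per-sample multiplier would cancel in within-sample TPM normalization, so
composition is the mechanism that makes the offsets observable — the same
mechanism by which a bloated annotation dilutes TPM in real data.

All randomness flows from ``SimConfig.seed`` through independent
``numpy.random.default_rng`` substreams, so identical configs reproduce
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .io_formats import (
    CountMatrix,
    HomologyTable,
    Term,
    TermMap,
    write_count_matrix,
    write_homology_table,
    write_sample_table,
    write_term_map,
)

__all__ = ["SimConfig", "SimTruth", "generate_truth", "simulate_counts", "write_fixture"]

DEFAULT_SPECIES = ("At", "Br", "Bn", "Hi")
DEFAULT_OFFSETS = {"At": 0.3, "Br": 0.05, "Bn": -0.3, "Hi": -0.05}


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic generator.

    Defaults mirror the design being emulated: 4 species x 2 treatments x
    5 replicates, NB dispersion 0.05, ~25% of groups responding to light,
    planted log2 effects around 1.5, and centered per-species baseline
    offsets (At highest, Bn lowest, Br/Hi intermediate).
    """

    species: Tuple[str, ...] = DEFAULT_SPECIES
    focal_species: str = "Hi"
    n_replicates: int = 5
    n_core_single: int = 1200
    n_core_multi: int = 200
    n_accessory: int = 800
    n_unique: int = 800
    baseline_offsets: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OFFSETS)
    )
    de_fraction: float = 0.25
    de_lfc_mean: float = 1.5
    de_lfc_sd: float = 0.4
    de_lfc_min: float = 0.8
    dispersion: float = 0.05
    library_size_mean: int = 2_000_000
    library_size_log_sd: float = 0.12
    planted_modes: Dict[str, int] = field(
        default_factory=lambda: {
            "treatment_DE": 30,
            "constitutive_high": 30,
            "cumulative_paralog": 30,
        }
    )
    planted_base_log2: float = 5.0
    planted_de_lfc: float = 1.5
    constitutive_margin_log2: float = 2.0
    cumulative_copy_factor: float = 1.1
    base_mean_log2: float = 3.0
    base_sd_log2: float = 2.0
    divergence_sd: float = 0.25
    ambiguous_fraction: float = 0.02
    private_mass_ratio: float = 1.0
    gene_length_mean: float = 1500.0
    gene_length_log_sd: float = 0.35
    seed: int = 17

    def __post_init__(self) -> None:
        for n in (self.n_core_single, self.n_core_multi, self.n_accessory,
                  self.n_unique, self.n_replicates):
            if n < 0:
                raise ValueError("counts must be >= 0")
        if self.focal_species not in self.species:
            raise ValueError("focal species must be one of the declared species")
        missing = set(self.species) - set(self.baseline_offsets)
        if missing:
            raise ValueError(f"baseline offsets missing for {sorted(missing)}")
        center = np.mean([self.baseline_offsets[s] for s in self.species])
        if abs(center) > 1e-9:
            # offsets are defined up to a common constant; center them
            self.baseline_offsets = {
                s: self.baseline_offsets[s] - center for s in self.species
            }
        if (
            self.planted_modes.get("treatment_DE", 0)
            + self.planted_modes.get("constitutive_high", 0)
            > self.n_core_single
            or self.planted_modes.get("cumulative_paralog", 0) > self.n_core_multi
        ):
            raise ValueError("planted modes exceed the available groups")

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if "species" in d:
            d["species"] = tuple(d["species"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["species"] = list(self.species)
        return d


@dataclass
class SimTruth:
    """Planted ground truth: per-gene parameters and group-level labels."""

    config: SimConfig
    genes: pd.DataFrame  # gene_id, species, group_id, base_log2, lfc, copy_index, length
    groups: pd.DataFrame  # group_id, membership, mode_label
    homology: HomologyTable

    @property
    def offsets(self) -> pd.Series:
        return pd.Series(
            {s: self.config.baseline_offsets[s] for s in self.config.species},
            name="baseline_offset",
        )

    def planted_mode_labels(self) -> pd.Series:
        lab = self.groups.set_index("group_id")["mode_label"]
        return lab[lab != "none"]


def _draw_lfc(rng: np.random.Generator, cfg: SimConfig) -> float:
    mag = abs(rng.normal(cfg.de_lfc_mean, cfg.de_lfc_sd))
    return max(mag, cfg.de_lfc_min)


def _core_pattern(rng: np.random.Generator, species: Tuple[str, ...]) -> Dict[str, int]:
    """Sign per species for a responsive core group (at least one nonzero)."""
    kind = rng.choice(
        ["all", "shared", "unique", "contrasting"], p=[0.12, 0.33, 0.40, 0.15]
    )
    sign = int(rng.choice([1, -1]))
    signs = {sp: 0 for sp in species}
    if kind == "all":
        signs = {sp: sign for sp in species}
    elif kind == "shared":
        k = int(rng.integers(2, len(species)))
        chosen = rng.choice(len(species), size=k, replace=False)
        for i in chosen:
            signs[species[i]] = sign
    elif kind == "unique":
        signs[species[int(rng.integers(len(species)))]] = sign
    else:  # contrasting: at least one + and one -
        while True:
            draw = rng.choice([1, -1, 0], size=len(species), p=[0.35, 0.35, 0.30])
            if (draw > 0).any() and (draw < 0).any():
                break
        signs = dict(zip(species, (int(x) for x in draw)))
    return signs


def generate_truth(cfg: SimConfig) -> SimTruth:
    """Build the homology structure and per-gene true expression parameters."""
    rng = np.random.default_rng([cfg.seed, 1])
    species = cfg.species
    focal = cfg.focal_species
    others = [s for s in species if s != focal]

    gene_rows: List[dict] = []
    group_rows: List[dict] = []
    homology: Dict[str, List[Tuple[str, str]]] = {}
    counters = {sp: 0 for sp in species}

    def new_gene(sp: str) -> str:
        counters[sp] += 1
        return f"{sp}_g{counters[sp]:05d}"

    def add_gene(sp, gid, base, lfc, copy_index) -> None:
        gene_rows.append(
            {
                "gene_id": new_gene(sp),
                "species": sp,
                "group_id": gid,
                "base_log2": base,
                "lfc": lfc,
                "copy_index": copy_index,
            }
        )
        homology[gid].append((sp, gene_rows[-1]["gene_id"]))

    n_de_planted = cfg.planted_modes.get("treatment_DE", 0)
    n_const = cfg.planted_modes.get("constitutive_high", 0)
    n_cum = cfg.planted_modes.get("cumulative_paralog", 0)
    gid_counter = 0

    def next_gid() -> str:
        nonlocal gid_counter
        gid_counter += 1
        return f"HG{gid_counter:05d}"

    # --- core single-copy groups (planted treatment_DE / constitutive first)
    for i in range(cfg.n_core_single):
        gid = next_gid()
        homology[gid] = []
        if i < n_de_planted:
            mode = "treatment_DE"
            base = rng.normal(cfg.planted_base_log2, 0.5)
            for sp in species:
                add_gene(sp, gid, base, cfg.planted_de_lfc if sp == focal else 0.0, 0)
        elif i < n_de_planted + n_const:
            mode = "constitutive_high"
            base = rng.normal(cfg.planted_base_log2, 0.5)
            for sp in species:
                margin = cfg.constitutive_margin_log2 if sp == focal else 0.0
                add_gene(sp, gid, base + margin, 0.0, 0)
        else:
            mode = "none"
            base = rng.normal(cfg.base_mean_log2, cfg.base_sd_log2)
            signs = (
                _core_pattern(rng, species)
                if rng.random() < cfg.de_fraction
                else {sp: 0 for sp in species}
            )
            for sp in species:
                lfc = signs[sp] * _draw_lfc(rng, cfg) if signs[sp] else 0.0
                add_gene(sp, gid, base + rng.normal(0, cfg.divergence_sd), lfc, 0)
        group_rows.append({"group_id": gid, "membership": "core", "mode_label": mode})

    # --- core multi-copy groups (focal paralog expansions; planted cumulative first)
    for i in range(cfg.n_core_multi):
        gid = next_gid()
        homology[gid] = []
        if i < n_cum:
            mode = "cumulative_paralog"
            base = rng.normal(cfg.planted_base_log2, 0.5)
            n_copies = int(rng.integers(3, 5))
            for sp in others:
                add_gene(sp, gid, base, 0.0, 0)
            for c in range(n_copies):
                add_gene(focal, gid, base + np.log2(cfg.cumulative_copy_factor), 0.0, c)
        else:
            mode = "none"
            base = rng.normal(cfg.base_mean_log2, cfg.base_sd_log2)
            n_copies = int(rng.integers(2, 5))
            responsive = rng.random() < cfg.de_fraction
            signs = _core_pattern(rng, species) if responsive else {sp: 0 for sp in species}
            lfcs = {
                sp: signs[sp] * _draw_lfc(rng, cfg) if signs[sp] else 0.0
                for sp in species
            }
            for sp in others:
                add_gene(sp, gid, base + rng.normal(0, cfg.divergence_sd), lfcs[sp], 0)
            flip = (
                signs[focal] != 0
                and n_copies >= 2
                and rng.random() < cfg.ambiguous_fraction
            )
            for c in range(n_copies):
                lfc = lfcs[focal]
                if flip and c == 0 and lfc != 0:
                    lfc = -lfc  # one discordant copy -> ambiguous group
                # copies split the group's expression budget
                add_gene(
                    focal,
                    gid,
                    base - np.log2(n_copies) + rng.normal(0, cfg.divergence_sd),
                    lfc,
                    c,
                )
        group_rows.append({"group_id": gid, "membership": "core", "mode_label": mode})

    # --- accessory groups (2-3 of the focal species)
    for _ in range(cfg.n_accessory):
        gid = next_gid()
        homology[gid] = []
        k = int(rng.integers(2, len(species)))
        members = [species[i] for i in rng.choice(len(species), size=k, replace=False)]
        base = rng.normal(cfg.base_mean_log2, cfg.base_sd_log2)
        responsive = rng.random() < cfg.de_fraction
        if responsive:
            sign = int(rng.choice([1, -1]))
            resp = {sp: sign if rng.random() < 0.6 else 0 for sp in members}
            if all(v == 0 for v in resp.values()):
                resp[members[0]] = sign
        else:
            resp = {sp: 0 for sp in members}
        for sp in members:
            lfc = resp[sp] * _draw_lfc(rng, cfg) if resp[sp] else 0.0
            add_gene(sp, gid, base + rng.normal(0, cfg.divergence_sd), lfc, 0)
        group_rows.append(
            {"group_id": gid, "membership": "accessory", "mode_label": "none"}
        )

    # --- unique groups (round-robin across species, occasional paralog pair)
    for i in range(cfg.n_unique):
        gid = next_gid()
        homology[gid] = []
        sp = species[i % len(species)]
        base = rng.normal(cfg.base_mean_log2, cfg.base_sd_log2)
        n_copies = 2 if rng.random() < 0.3 else 1
        lfc_sp = (
            int(rng.choice([1, -1])) * _draw_lfc(rng, cfg)
            if rng.random() < cfg.de_fraction
            else 0.0
        )
        for c in range(n_copies):
            add_gene(sp, gid, base + rng.normal(0, cfg.divergence_sd), lfc_sp, c)
        group_rows.append(
            {"group_id": gid, "membership": "unique", "mode_label": "none"}
        )

    genes = pd.DataFrame(gene_rows)
    groups = pd.DataFrame(group_rows)

    # --- plant baseline offsets via private-transcriptome composition.
    # A gene's TPM is its share of the species' total transcript rate mass,
    # so the observable cross-species offset for core genes is set by each
    # species' total composition, averaged over the two treatments (the
    # baseline is estimated from treatment-pooled means). We rescale the
    # species-private (accessory+unique) mass so that the pooled harmonic
    # composition H_s = 2 / (1/D_LL + 1/D_HL) satisfies
    # H_s = K * 2^(-offset_s) exactly, for a common constant K.
    core_ids = set(groups.loc[groups["membership"] == "core", "group_id"])
    is_core = genes["group_id"].isin(core_ids).to_numpy()
    mass_ll = 2.0 ** genes["base_log2"].to_numpy()
    mass_hl = 2.0 ** (genes["base_log2"] + genes["lfc"]).to_numpy()
    comp = {}
    for sp in species:
        sp_sel = (genes["species"] == sp).to_numpy()
        comp[sp] = {
            "C_LL": mass_ll[sp_sel & is_core].sum(),
            "C_HL": mass_hl[sp_sel & is_core].sum(),
            "P_LL": mass_ll[sp_sel & ~is_core].sum(),
            "P_HL": mass_hl[sp_sel & ~is_core].sum(),
        }

    def pooled_h(c, t):
        d_ll = c["C_LL"] + t * c["P_LL"]
        d_hl = c["C_HL"] + t * c["P_HL"]
        return 2.0 / (1.0 / d_ll + 1.0 / d_hl)

    core_h = float(np.mean([pooled_h(comp[sp], 0.0) for sp in species]))
    target_k = core_h * (1.0 + cfg.private_mass_ratio)
    for sp in species:
        target = target_k * 2.0 ** (-cfg.baseline_offsets[sp])
        if target <= pooled_h(comp[sp], 0.0):
            raise ValueError(
                "planted offset for "
                f"{sp!r} needs negative private mass; increase private_mass_ratio"
            )
        t = brentq(
            lambda t: pooled_h(comp[sp], t) - target, 1e-9, 1e9, xtol=1e-12
        )
        sel = (genes["species"] == sp).to_numpy() & ~is_core
        genes.loc[sel, "base_log2"] += np.log2(t)

    # --- gene lengths (log-normal around ~1.5 kb)
    lengths = rng.lognormal(
        np.log(cfg.gene_length_mean), cfg.gene_length_log_sd, size=len(genes)
    )
    genes["length"] = np.maximum(lengths.astype(np.int64), 200)

    return SimTruth(config=cfg, genes=genes, groups=groups,
                    homology=HomologyTable(groups=homology))


def simulate_counts(
    truth: SimTruth, cfg: Optional[SimConfig] = None
) -> Tuple[Dict[str, CountMatrix], pd.DataFrame]:
    """Draw NB count matrices and the sample table from planted truth.

    Per gene and sample, mean = library_factor x 2^(base + treatment*lfc)
    x length/1e3, normalized per species so that column sums track the
    configured library size; dispersion is ``cfg.dispersion`` (Poisson in
    the limit alpha -> 0).
    """
    cfg = cfg or truth.config
    rng = np.random.default_rng([cfg.seed, 2])
    sample_rows = []
    for sp in cfg.species:
        for trt in ("HL", "LL"):
            for r in range(1, cfg.n_replicates + 1):
                sample_rows.append(
                    {
                        "sample_id": f"{sp}_{trt}_{r}",
                        "species_id": sp,
                        "treatment": trt,
                        "replicate": r,
                    }
                )
    samples = pd.DataFrame(sample_rows)

    matrices: Dict[str, CountMatrix] = {}
    for sp in cfg.species:
        sub = truth.genes[truth.genes["species"] == sp]
        base = sub["base_log2"].to_numpy()
        lfc = sub["lfc"].to_numpy()
        length = sub["length"].to_numpy(dtype=float)
        sp_samples = samples[samples["species_id"] == sp]
        # LL composition defines the species' normalizing constant
        norm = (2.0**base * length / 1e3).sum()
        cols = {}
        for _, row in sp_samples.iterrows():
            lib = rng.lognormal(np.log(cfg.library_size_mean), cfg.library_size_log_sd)
            expr = base + (lfc if row["treatment"] == "HL" else 0.0)
            mu = lib * (2.0**expr * length / 1e3) / norm
            if cfg.dispersion < 1e-8:
                cols[row["sample_id"]] = rng.poisson(mu)
            else:
                r_nb = 1.0 / cfg.dispersion
                cols[row["sample_id"]] = rng.negative_binomial(r_nb, r_nb / (r_nb + mu))
        counts = pd.DataFrame(cols, index=sub["gene_id"].to_numpy())
        counts.index.name = "gene_id"
        matrices[sp] = CountMatrix(
            species_id=sp,
            counts=counts,
            gene_lengths=pd.Series(
                sub["length"].to_numpy(), index=sub["gene_id"].to_numpy()
            ),
        )
    return matrices, samples


def _build_term_map(
    truth: SimTruth, reference_species: str = "At", n_random_terms: int = 25
) -> TermMap:
    """Term map concentrating planted treatment-DE genes in one term."""
    rng = np.random.default_rng([truth.config.seed, 3])
    ref_genes = truth.genes.loc[
        truth.genes["species"] == reference_species, "gene_id"
    ].to_numpy()
    planted_groups = set(
        truth.groups.loc[
            truth.groups["mode_label"] == "treatment_DE", "group_id"
        ]
    )
    planted_genes = truth.genes[
        (truth.genes["species"] == reference_species)
        & truth.genes["group_id"].isin(planted_groups)
    ]["gene_id"].tolist()
    terms: TermMap = {}
    if planted_genes:
        terms["TERM_PLANTED_DE"] = Term(
            "TERM_PLANTED_DE",
            "planted high-light response module",
            frozenset(planted_genes),
        )
    for i in range(n_random_terms):
        size = int(rng.integers(10, 61))
        genes = rng.choice(ref_genes, size=size, replace=False)
        tid = f"TERM_{i + 1:04d}"
        terms[tid] = Term(tid, f"random gene set {i + 1}", frozenset(genes))
    return terms


def write_fixture(out_dir, cfg: Optional[SimConfig] = None, force: bool = False) -> dict:
    """Generate and write a complete fixture (counts, lengths, samples,
    homology, truth, term map, config) to ``out_dir``.

    Refuses to write into an existing non-empty directory unless ``force``.
    Returns a manifest of the written paths plus the in-memory truth.
    """
    cfg = cfg or SimConfig()
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists and is not empty (use force=True)")
    out.mkdir(parents=True, exist_ok=True)

    truth = generate_truth(cfg)
    matrices, samples = simulate_counts(truth, cfg)
    paths = {}
    for sp, cm in matrices.items():
        paths[f"counts_{sp}"] = str(out / f"counts_{sp}.tsv")
        paths[f"lengths_{sp}"] = str(out / f"lengths_{sp}.tsv")
        write_count_matrix(cm, paths[f"counts_{sp}"], paths[f"lengths_{sp}"])
    paths["samples"] = str(out / "samples.tsv")
    write_sample_table(samples, paths["samples"])
    paths["homology"] = str(out / "homology.tsv")
    write_homology_table(truth.homology, paths["homology"])
    paths["terms"] = str(out / "terms.tsv")
    write_term_map(_build_term_map(truth), paths["terms"])
    paths["truth_genes"] = str(out / "truth_genes.tsv")
    truth.genes.to_csv(paths["truth_genes"], sep="\t", index=False)
    paths["truth_groups"] = str(out / "truth_groups.tsv")
    truth.groups.to_csv(paths["truth_groups"], sep="\t", index=False)
    paths["truth_offsets"] = str(out / "truth_offsets.tsv")
    truth.offsets.rename_axis("species_id").to_frame().to_csv(
        paths["truth_offsets"], sep="\t"
    )
    paths["config"] = str(out / "sim_config.yaml")
    with open(paths["config"], "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
    return {"paths": paths, "truth": truth, "matrices": matrices, "samples": samples}
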