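"""End-to-end orchestration: incidence -> richness -> similarity -> beta
-> ecotone -> partition comparison, from a single configuration.

Every stage writes plain-text artifacts (TSV/JSON/Newick) into the output
directory plus a run log recording the seed, stage-level dropped-record
counts and package version.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .beta import baselga_multisite, baselga_pair, carvalho_multisite, carvalho_pair, distance_decay, upgma
from .compare import compare_partitions, match_percentage
from .data_model import SpecimenTable, build_incidence, read_specimen_table
from .ecotone import detect_ecotone, slice_elevation, sliding_profile
from .errors import ConfigError, GradcommError
from .richness import estimate_all
from .similarity import combined_table, pair_counts, similarity_matrix
from .synthetic import GradientCommunityConfig, generate_gradient_community

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    hypothesis: str
    output_dir: str
    input_table: str | None = None                 # CSV path, or
    synthetic: GradientCommunityConfig | None = None
    unit_definitions: list = field(default_factory=lambda: ["locality", "path"])
    biome_threshold: float = 300.0
    bin_width: float = 40.0
    exclude_paths: list[str] = field(default_factory=lambda: ["DH"])
    exclude_singletons: bool = False
    beta_families: list[str] = field(default_factory=lambda: ["baselga", "carvalho"])
    rarefaction_factor: float = 3.0
    n_boot: int = 100
    reference_hypothesis: str | None = None        # for partition comparison
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "synthetic" in d and d["synthetic"] is not None:
            syn = d["synthetic"]
            for key in ("dry_center", "moist_center", "range_width", "ecotone_band"):
                syn[key] = tuple(syn[key])
            syn["localities"] = [tuple(t) for t in syn["localities"]]
            d["synthetic"] = GradientCommunityConfig(**syn)
        return cls(**d)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and return a manifest of written artifacts."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    log: dict[str, object] = {"version": __version__, "seed": cfg.seed, "stages": {}}
    rng = np.random.default_rng(cfg.seed)
    substreams = rng.spawn(4)  # fixed per-stage substreams

    stage = "load"
    try:
        if cfg.synthetic is not None:
            table, truth = generate_gradient_community(cfg.synthetic)
            truth.to_json(out / "ground_truth.json")
            table.to_csv(out / "specimens.csv")
            manifest["specimens"] = "specimens.csv"
            manifest["ground_truth"] = "ground_truth.json"
        elif cfg.input_table:
            table = read_specimen_table(cfg.input_table)
        else:
            raise ConfigError("pipeline needs input_table or a synthetic config")
        if cfg.hypothesis not in table.hypotheses:
            raise ConfigError(
                f"hypothesis column {cfg.hypothesis!r} absent; available: {table.hypotheses}"
            )
        n_before = len(table)
        if cfg.exclude_paths:
            table = table.subset(lambda r: r.path not in set(cfg.exclude_paths))
        log["stages"]["load"] = {"records": len(table), "excluded_by_path": n_before - len(table)}

        stage = "incidence"
        matrices = {}
        for ud in cfg.unit_definitions + [("biome", cfg.biome_threshold)]:
            X = build_incidence(table, cfg.hypothesis, _parse_ud(ud))
            key = X.unit_definition.replace("(", "_").replace(")", "").replace(".", "_")
            fname = f"incidence_{key}.tsv"
            X.to_tsv(out / fname)
            matrices[X.unit_definition] = X
            manifest[f"incidence:{X.unit_definition}"] = fname
        log["stages"]["incidence"] = {k: v.cells.shape for k, v in matrices.items()}

        stage = "richness"
        rows = []
        for name, X in matrices.items():
            if X.n_units < 2:
                continue
            ests = estimate_all(X, cfg.rarefaction_factor, cfg.n_boot, substreams[0])
            row = {"partition": name, "m": X.n_units}
            for key, est in ests.items():
                row[key] = round(est.value, 1)
                if est.sd is not None:
                    row[f"{key}_sd"] = round(est.sd, 2)
            rows.append(row)
        pd.DataFrame(rows).to_csv(out / "richness.tsv", sep="\t", index=False)
        manifest["richness"] = "richness.tsv"

        stage = "similarity"
        Xp = matrices.get("path") or next(iter(matrices.values()))
        combo = combined_table(Xp)
        pd.DataFrame(combo, index=Xp.units, columns=Xp.units).to_csv(
            out / "similarity.tsv", sep="\t", float_format="%.3f"
        )
        manifest["similarity"] = "similarity.tsv"

        stage = "beta"
        beta_rows = []
        sets = {u: Xp.species_set(u) for u in Xp.units}
        for i, a in enumerate(Xp.units):
            for b in Xp.units[i + 1:]:
                pc = pair_counts(sets[a], sets[b])
                for fam in cfg.beta_families:
                    d = baselga_pair(pc) if fam == "baselga" else carvalho_pair(pc)
                    beta_rows.append(
                        {
                            "pair": f"{a}-{b}", "family": d.family,
                            "total": round(d.total, 4), "turnover": round(d.turnover, 4),
                            "nestedness_or_richness": round(d.nestedness_or_richness, 4),
                        }
                    )
        for fam in cfg.beta_families:
            d = baselga_multisite(Xp) if fam == "baselga" else carvalho_multisite(Xp)
            beta_rows.append(
                {
                    "pair": d.scope, "family": d.family,
                    "total": round(d.total, 4), "turnover": round(d.turnover, 4),
                    "nestedness_or_richness": round(d.nestedness_or_richness, 4),
                }
            )
        pd.DataFrame(beta_rows).to_csv(out / "beta.tsv", sep="\t", index=False)
        manifest["beta"] = "beta.tsv"

        sim = similarity_matrix(Xp, "sorensen")
        dend = upgma(sim.to_dissimilarity(), list(Xp.units))
        (out / "dendrogram.nwk").write_text(dend.to_newick() + "\n")
        manifest["dendrogram"] = "dendrogram.nwk"

        if len(table.localities) >= 3:
            dd = distance_decay(table, cfg.hypothesis)
            pd.DataFrame(
                dd.pairs, columns=["unit_a", "unit_b", "km", "similarity"]
            ).to_csv(out / "distance_decay.tsv", sep="\t", index=False)
            manifest["distance_decay"] = "distance_decay.tsv"
            log["stages"]["beta"] = {"decay_slope": dd.slope}

        stage = "ecotone"
        bins = slice_elevation(table, cfg.hypothesis, cfg.bin_width)
        profile = sliding_profile(bins, exclude_singletons=cfg.exclude_singletons)
        pd.DataFrame(
            [
                {
                    "boundary_elev": c.boundary, "shared_index": round(c.shared_index, 4),
                    "below_excl": c.below_exclusive, "above_excl": c.above_exclusive,
                }
                for c in profile.comparisons
            ]
        ).to_csv(out / "ecotone_profile.tsv", sep="\t", index=False)
        call = detect_ecotone(profile)
        (out / "ecotone_call.json").write_text(
            json.dumps(
                {
                    "detected": call.detected,
                    "transition_interval": call.transition_interval,
                    "boundary": call.boundary,
                    "diagnostics": call.diagnostics,
                    "confidence_note": call.confidence_note,
                },
                indent=2,
            )
        )
        manifest["ecotone_profile"] = "ecotone_profile.tsv"
        manifest["ecotone_call"] = "ecotone_call.json"

        stage = "compare"
        ref = cfg.reference_hypothesis
        if ref is None and "morphospecies" in table.hypotheses and cfg.hypothesis != "morphospecies":
            ref = "morphospecies"
        if ref and ref in table.hypotheses and ref != cfg.hypothesis:
            cmpres = compare_partitions(table, ref, cfg.hypothesis)
            (out / "comparison.json").write_text(
                json.dumps(
                    {
                        "reference": cmpres.reference, "test": cmpres.test,
                        "n_reference_species": cmpres.n_reference_species,
                        "agree": cmpres.agree, "split": cmpres.split,
                        "merge": cmpres.merge, "complex": cmpres.complex,
                        "match_percentage": round(match_percentage(cmpres), 1),
                    },
                    indent=2,
                )
            )
            manifest["comparison"] = "comparison.json"
    except GradcommError as exc:
        raise GradcommError(f"pipeline stage {stage!r} failed: {exc}") from exc

    log["artifacts"] = manifest
    (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    manifest["run_log"] = "run_log.json"
    return manifest


def _parse_ud(ud):
    if isinstance(ud, str) and ud.startswith("elevation_bin:"):
        return ("elevation_bin", float(ud.split(":", 1)[1]))
    if isinstance(ud, str) and ud.startswith("biome:"):
        return ("biome", float(ud.split(":", 1)[1]))
    if isinstance(ud, list) and len(ud) == 2:
        return (ud[0], float(ud[1]))
    return ud
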