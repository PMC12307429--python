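"""End-to-end pipeline driver with strict config and a run manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

logger = logging.getLogger(__name__)

STAGES = ("stats", "filter", "tree", "pca", "core", "diversity",
          "fingerprint")


class ConfigError(ValueError):
    """Invalid or unknown pipeline configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; message names the stage."""


def _check_keys(section: str, given: dict, allowed: set) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) in {section!r}: {sorted(unknown)} "
            f"(allowed: {sorted(allowed)})"
        )


@dataclass
class RunConfig:
    """Validated pipeline configuration (YAML-friendly).

    Either ``input_vcf`` or a ``simulate`` section must be present.
    Unknown keys anywhere are rejected.  Per-stage seeds are derived
    deterministically from ``seed`` (seed + stage index) so any stage can
    be rerun in isolation.
    """

    outdir: Path
    seed: int = 0
    log_level: str = "INFO"
    input_vcf: Path | None = None
    simulate: dict | None = None
    filter: dict = field(default_factory=dict)
    tree: dict = field(default_factory=dict)
    pca: dict = field(default_factory=dict)
    core: dict = field(default_factory=dict)
    diversity: dict = field(default_factory=dict)
    fingerprint: dict = field(default_factory=dict)

    _ALLOWED = {
        "top": {"outdir", "seed", "log_level", "input_vcf", "simulate",
                "filter", "tree", "pca", "core", "diversity", "fingerprint"},
        "simulate": {"n_accessions", "n_snps", "n_indels", "n_subpops",
                     "divergence", "admixture_fraction", "maf_floor",
                     "missing_rate", "indel_max_len", "chrom_count",
                     "chrom_length", "fail_fraction"},
        "filter": {"maf_min", "max_missing", "biallelic_snps_only"},
        "tree": {"bootstrap"},
        "pca": {"components"},
        "core": {"target_coverage", "target_size", "coverage_gain_floor"},
        "diversity": {"proportions"},
        "fingerprint": {"method", "population_size", "generations",
                        "crossover_rate", "mutation_rate",
                        "tournament_size", "elitism", "size_penalty"},
    }

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.input_vcf is not None:
            self.input_vcf = Path(self.input_vcf)
            if not self.input_vcf.exists():
                raise ConfigError(f"input_vcf does not exist: {self.input_vcf}")
        if self.input_vcf is None and not self.simulate_enabled:
            raise ConfigError("config needs either input_vcf or simulate:")
        for section in ("simulate", "filter", "tree", "pca", "core",
                        "diversity", "fingerprint"):
            value = getattr(self, section)
            if value is None:
                continue
            if not isinstance(value, dict):
                raise ConfigError(f"section {section!r} must be a mapping")
            _check_keys(section, value, self._ALLOWED[section])

    @property
    def simulate_enabled(self) -> bool:
        return self.simulate is not None

    def stage_seed(self, stage: str) -> int:
        idx = (("simulate",) + STAGES).index(stage)
        return int(self.seed) + idx

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text())
        except OSError as e:
            raise ConfigError(f"cannot read config {path}: {e}") from e
        except yaml.YAMLError as e:
            raise ConfigError(f"invalid YAML in {path}: {e}") from e
        if not isinstance(raw, dict):
            raise ConfigError("config must be a YAML mapping")
        _check_keys("top level", raw, cls._ALLOWED["top"])
        if "outdir" not in raw:
            raise ConfigError("config is missing required key 'outdir'")
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute simulate? -> stats -> filter -> tree/pca -> core ->
    diversity -> fingerprint and write ``manifest.json``.

    Returns the output directory.  Any stage failure raises
    :class:`StageError` naming the stage; outputs of completed stages are
    retained.
    """
    from . import (core_select, diversity, fingerprint, genotype_matrix,
                   popstruct, synthetic_data, variant_io)

    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": int(config.seed), "stages": [], "seeds": {},
                      "outputs": {}, "parameters": {}}

    def record(stage: str, params: dict, *paths: Path) -> None:
        manifest["stages"].append(stage)
        manifest["parameters"][stage] = {
            k: (str(v) if isinstance(v, Path) else v) for k, v in params.items()}
        for p in paths:
            manifest["outputs"][str(p.relative_to(out))] = _sha256(p)

    current_stage = "setup"
    try:
        # ---------------------------------------------------- simulate
        if config.simulate_enabled:
            current_stage = "simulate"
            sim_kwargs = dict(config.simulate)
            fail_fraction = sim_kwargs.pop("fail_fraction", 0.0)
            pcfg = synthetic_data.PopulationConfig(
                seed=config.stage_seed("simulate"), **sim_kwargs)
            panel = synthetic_data.simulate_panel(pcfg)
            vcf_path = out / "simulated.vcf"
            truth = synthetic_data.write_vcf(
                panel, pcfg, vcf_path, fail_fraction=fail_fraction)
            truth.to_csv(out / "simulated.truth.tsv", sep="\t")
            manifest["seeds"]["simulate"] = pcfg.seed
            record("simulate", sim_kwargs, vcf_path,
                   out / "simulated.truth.tsv")
            input_vcf = vcf_path
        else:
            input_vcf = config.input_vcf

        # -------------------------------------------------------- stats
        current_stage = "stats"
        samples, records = variant_io.read_vcf(input_vcf)
        summary = variant_io.summarize_variants(records)
        stats_path = out / "variant_summary.json"
        stats_path.write_text(json.dumps(summary.to_dict(), indent=2))
        record("stats", {"input": input_vcf}, stats_path)

        # ------------------------------------------------------- filter
        current_stage = "filter"
        matrix = genotype_matrix.from_vcf(records, samples)
        filtered, audit = genotype_matrix.site_filter(matrix,
                                                      **config.filter)
        audit_path = out / "filter_audit.tsv"
        audit.to_csv(audit_path, sep="\t")
        dosage_path = out / "filtered_dosages.tsv"
        filtered.to_tsv(dosage_path)
        record("filter", config.filter, audit_path, dosage_path)

        # --------------------------------------------------------- tree
        current_stage = "tree"
        n_boot = int(config.tree.get("bootstrap", 0))
        if n_boot:
            tree = popstruct.bootstrap_support(
                filtered, n_reps=n_boot, seed=config.stage_seed("tree"))
            manifest["seeds"]["tree"] = config.stage_seed("tree")
        else:
            tree = popstruct.nj(popstruct.squared_distance(filtered))
        tree_path = out / "nj_tree.nwk"
        tree.write(path=str(tree_path), schema="newick",
                   suppress_rooting=True)
        record("tree", {"bootstrap": n_boot}, tree_path)

        # ---------------------------------------------------------- pca
        current_stage = "pca"
        k = int(config.pca.get("components", 10))
        k = min(k, filtered.n_samples)
        pca_res = popstruct.pca(popstruct.grm(filtered), k=k,
                                sample_ids=filtered.sample_ids)
        import pandas as pd

        coords = pd.DataFrame(
            pca_res.coordinates, index=pca_res.sample_ids,
            columns=[f"PC{i + 1}" for i in range(k)])
        pca_path = out / "pca_coordinates.tsv"
        coords.to_csv(pca_path, sep="\t", index_label="sample")
        var_path = out / "pca_variance.tsv"
        pd.Series(pca_res.variance_explained,
                  index=coords.columns, name="variance_explained"
                  ).to_csv(var_path, sep="\t")
        record("pca", {"components": k}, pca_path, var_path)

        # --------------------------------------------------------- core
        current_stage = "core"
        core_res = core_select.greedy_core(filtered, **config.core)
        core_path = out / "core_accessions.txt"
        core_path.write_text("\n".join(core_res.selected) + "\n")
        traj_path = out / "core_trajectory.tsv"
        pd.DataFrame({
            "size": range(1, core_res.final_size + 1),
            "coverage": core_res.coverage_trajectory,
        }).to_csv(traj_path, sep="\t", index=False)
        record("core", config.core, core_path, traj_path)

        # ---------------------------------------------------- diversity
        current_stage = "diversity"
        div_seed = config.stage_seed("diversity")
        table = diversity.sampling_evaluation(
            filtered, core_res.selected,
            proportions=config.diversity.get("proportions",
                                             (10, 25, 50, 75, 100)),
            seed=div_seed)
        manifest["seeds"]["diversity"] = div_seed
        div_path = out / "diversity_table.tsv"
        table.to_csv(div_path, sep="\t", index=False)
        record("diversity", config.diversity, div_path)

        # -------------------------------------------------- fingerprint
        current_stage = "fingerprint"
        fp_kwargs = dict(config.fingerprint)
        method = fp_kwargs.pop("method", "ga")
        candidates = fingerprint.candidate_filter(filtered)
        fp_seed = config.stage_seed("fingerprint")
        if method == "ga":
            panel_res = fingerprint.ga_select(
                filtered, candidates,
                fingerprint.GaParams(seed=fp_seed, **fp_kwargs))
            manifest["seeds"]["fingerprint"] = fp_seed
        elif method == "greedy":
            panel_res = fingerprint.greedy_select(filtered, candidates)
        elif method == "exact":
            panel_res = fingerprint.exhaustive_min(filtered, candidates)
        else:
            raise ConfigError(f"unknown fingerprint method {method!r}")
        table = fingerprint.fingerprint_table(filtered, panel_res)
        fp_path = out / "fingerprint_matrix.tsv"
        table.to_csv(fp_path, sep="\t", index_label="locus_id")
        sites_path = out / "fingerprint_sites.tsv"
        filtered.loci.loc[panel_res.loci, ["chrom", "pos", "ref", "alt"]
                          ].to_csv(sites_path, sep="\t")
        codes_path = out / "fingerprint_codes.tsv"
        pd.Series(panel_res.codes, name="code").to_csv(
            codes_path, sep="\t", index_label="sample")
        record("fingerprint", {"method": method, **fp_kwargs},
               fp_path, sites_path, codes_path)

    except ConfigError:
        raise
    except Exception as e:
        raise StageError(f"stage {current_stage!r} failed: {e}") from e

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline complete: %d stages, outputs in %s",
                len(manifest["stages"]), out)
    return out
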