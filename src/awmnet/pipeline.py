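"""End-to-end pipeline: simulate -> QC -> deregress -> GWAS -> mapping ->
AWM -> PCIT -> network statistics -> GRMs -> cross-validated prediction.

Configuration is a nested mapping (usually loaded from YAML) with one block
per stage; a single global seed is propagated deterministically, each stage
deriving its own sub-seed by a fixed offset.  Every output file carries a
header naming the package version, the config hash and the seed, and the
run writes a manifest of all artifacts with their SHA-256 hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as aio
from .awm import TraitGroups, awm_from_gwas
from .deregress import deregress, filter_records
from .gblup import GBLUPConfig, kmeans_families, run_cross_validation
from .grm import a_matrix, build_all_grms
from .gwas import BayesBConfig, gwas_all_traits, qc_markers
from .mapping import genes_in_qtl, map_snp_to_genes
from .netstats import hub_report, intersect_networks, powerlaw_ks_test
from .pcit import pcit, row_correlations, trim_network, write_edgelist
from .simulate import SimConfig, simulate_all

log = logging.getLogger(__name__)

_SEED_OFFSETS = {"simulate": 0, "gwas": 100, "cv": 200, "netstats": 300}


@dataclass
class PipelineConfig:
    outdir: str = "awmnet_out"
    seed: int = 0
    simulate: dict | None = None          # SimConfig fields; None -> read paths
    paths: dict = field(default_factory=dict)
    deregress: dict = field(default_factory=dict)
    gwas: dict = field(default_factory=dict)
    mapping: dict = field(default_factory=dict)
    awm: dict = field(default_factory=dict)
    pcit: dict = field(default_factory=dict)
    cv: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self):
        if self.simulate is None:
            required = {"genotypes", "map", "evaluations", "genes", "qtl", "pedigree"}
            missing = required - set(self.paths)
            if missing:
                raise ValueError(
                    "simulation disabled and input paths missing: " + ", ".join(sorted(missing))
                )
            for key, p in self.paths.items():
                if not Path(p).exists():
                    raise ValueError(f"configured path for {key!r} does not exist: {p}")

    def hash(self) -> str:
        # outdir is a run location, not an analysis parameter
        return aio.config_hash(
            {k: getattr(self, k) for k in self.__dataclass_fields__ if k != "outdir"}
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_inputs(config: PipelineConfig) -> dict:
    from .simulate import BreedData, GenotypeMatrix, TrueValues

    if config.simulate is not None:
        sim = SimConfig(**{**config.simulate, "seed": config.seed + _SEED_OFFSETS["simulate"]})
        return simulate_all(sim)
    codes = aio.read_genotypes(config.paths["genotypes"])
    geno = GenotypeMatrix(
        codes, aio.read_map(config.paths["map"]), codes.mean(axis=0, skipna=True) / 2.0
    )
    return {
        "input": BreedData(
            name="input",
            pedigree=aio.read_pedigree(config.paths["pedigree"]),
            genotypes=geno,
            genes=aio.read_intervals(config.paths["genes"]),
            qtl=aio.read_intervals(config.paths["qtl"]),
            evaluations=aio.read_evaluations(config.paths["evaluations"]),
            truth=None,
            config=None,
        )
    }


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage for every breed; returns the run report."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    hdr = dict(seed=config.seed, config_hash=config.hash())
    report = {"breeds": {}, "config_hash": config.hash(), "seed": config.seed}

    breeds = _load_inputs(config)
    networks = {}
    n_genes_mapped = {}

    for name, data in breeds.items():
        bdir = outdir / name
        bdir.mkdir(exist_ok=True)
        stage = "simulate/io"
        try:
            aio.write_pedigree(data.pedigree, bdir / "pedigree.tsv", **hdr)
            aio.write_genotypes(data.genotypes.codes, bdir / "genotypes.tsv", **hdr)
            aio.write_map(data.genotypes.marker_map, bdir / "markers.map.tsv", **hdr)
            aio.write_intervals(data.genes, bdir / "genes.tsv", **hdr)
            aio.write_intervals(data.qtl, bdir / "qtl.tsv", **hdr)
            aio.write_evaluations(data.evaluations, bdir / "evaluations.tsv", **hdr)

            stage = "qc"
            geno = qc_markers(data.genotypes, **config.gwas.get("qc", {}))

            stage = "deregress"
            dcfg = dict(config.deregress)
            min_rel = dcfg.pop("min_rel", 0.2)
            dreg = filter_records(deregress(data.evaluations, **dcfg), min_rel=min_rel)
            kept_bulls = [b for b in geno.bulls if b in set(dreg["bull"])]
            geno = geno.subset_bulls(kept_bulls)
            aio.write_evaluations(dreg, bdir / "deregressed.tsv", **hdr)

            stage = "gwas"
            gcfg = BayesBConfig(**{**config.gwas.get("bayesb", {}),
                                   "seed": config.seed + _SEED_OFFSETS["gwas"]})
            summaries = gwas_all_traits(dreg, geno, gcfg)
            for trait, s in summaries.items():
                tab = s.table.copy()
                tab.insert(0, "marker", tab.index)
                aio.write_table(tab, bdir / f"gwas_{trait}.tsv", **hdr)

            stage = "mapping"
            snp_gene = map_snp_to_genes(geno.marker_map, data.genes,
                                        **config.mapping)
            gene_qtl = genes_in_qtl(data.genes, data.qtl)
            aio.write_table(snp_gene, bdir / "snp_gene_map.tsv", **hdr)
            aio.write_table(gene_qtl, bdir / "gene_qtl.tsv", **hdr)
            n_genes_mapped[name] = snp_gene["gene"].nunique()

            stage = "awm"
            awm = awm_from_gwas(summaries, snp_gene, geno.marker_map,
                                **config.awm)
            out = awm.matrix.copy()
            out.insert(0, "source_marker", awm.source_marker)
            out.insert(0, "row", out.index)
            aio.write_table(out, bdir / "awm.tsv", **hdr)

            stage = "pcit"
            trim = config.pcit.get("trim", 0.98)
            network = trim_network(pcit(row_correlations(awm.matrix)), trim)
            networks[name] = network
            write_edgelist(network, bdir / "network_edges.tsv")

            stage = "netstats"
            degrees = [d for _, d in network.degree if d >= 1]
            pl = None
            if len(degrees) >= 10 and len(set(degrees)) > 1:
                pl = powerlaw_ks_test(degrees, seed=config.seed + _SEED_OFFSETS["netstats"])
            hubs = hub_report(network, gene_qtl, config.pcit.get("hub_top_fraction", 0.05))
            aio.write_table(hubs, bdir / "hubs.tsv", **hdr)

            stage = "grm/cv"
            pvg = pd.DataFrame({t: s.pvg for t, s in summaries.items()})
            grms = build_all_grms(geno, pvg, awm, network)
            A = a_matrix(data.pedigree)
            evaluated = list(geno.bulls)
            folds = kmeans_families(A.loc[evaluated, evaluated],
                                    k=config.cv.get("folds", 4),
                                    seed=config.seed + _SEED_OFFSETS["cv"])
            cv_cfg = GBLUPConfig(**{**config.cv.get("gblup", {}),
                                    "seed": config.seed + _SEED_OFFSETS["cv"]})
            cvres = run_cross_validation(
                dreg, geno, folds, snp_gene,
                models=config.cv.get("models", (1, 2, 3, 4, 5, 6, 7)),
                traits=config.cv.get("traits"),
                gwas_config=BayesBConfig(**{**config.gwas.get("bayesb", {}),
                                            "seed": config.seed + _SEED_OFFSETS["cv"]}),
                gblup_config=cv_cfg,
                trim_threshold=trim,
            )
            aio.write_table(cvres.per_fold, bdir / "cv_per_fold.tsv", **hdr)
            aio.write_table(cvres.summary, bdir / "cv_accuracy.tsv", **hdr)
        except Exception as err:
            inputs_hash = aio.config_hash({"breed": name})
            raise RuntimeError(f"stage {stage!r} failed for breed {name} "
                               f"(input hash {inputs_hash}): {err}") from err

        report["breeds"][name] = {
            "n_bulls": len(geno.bulls),
            "n_markers": len(geno.markers),
            "awm_rows": len(awm.rows),
            "network_edges": network.number_of_edges(),
            "powerlaw": pl,
            "grms": sorted(grms),
            "cv_accuracy": cvres.summary.to_dict("records"),
        }

    if len(networks) >= 2:
        universe = max(n_genes_mapped.values())
        inter = intersect_networks(networks, universe_n=universe)
        report["intersection"] = {
            "sizes": inter.set_sizes,
            "observed": inter.observed_k,
            "universe": inter.universe_n,
            "p_value": inter.p_value,
        }

    manifest = {
        str(p.relative_to(outdir)): _sha256(p)
        for p in sorted(outdir.rglob("*.tsv"))
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    (outdir / "report.json").write_text(json.dumps(report, indent=1, default=float))
    return report
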