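"""End-to-end orchestration: simulate or load genotypes, call crossovers,
build and compare maps, analyse tetrads, annotate alleles, write a report
bundle.

Every stage is a pure function of (inputs, config, seed); the manifest
written alongside the bundle records the config hash, seed, and package
version, and suffices to reproduce the bundle byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__, study, xo_map, xo_stats
from .gene_model import annotate_effect, read_gene_record
from .genotype_io import (GenotypeMatrix, MarkerTable, read_genotype_matrix,
                          read_marker_table, write_genotype_matrix,
                          write_marker_table)
from .meiosis_sim import simulate_population, tetrads_to_frame
from .reference_gene import allele_specs, build_reference_gene

logger = logging.getLogger("sporemap.pipeline")

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")


@dataclass(frozen=True)
class StrainInput:
    name: str
    simulate: Optional[dict] = None      # SimConfig-ish keys
    genotypes: Optional[str] = None      # path to genotype matrix TSV

    def __post_init__(self):
        if (self.simulate is None) == (self.genotypes is None):
            raise PipelineError(
                "config", f"strain {self.name!r}: exactly one of "
                "simulate/genotypes is required")


@dataclass(frozen=True)
class RunConfig:
    out_dir: str
    strains: tuple[StrainInput, StrainInput]
    seed: Optional[int] = None
    markers: Optional[str] = None        # marker table TSV; default: study design
    gene_record: Optional[str] = None    # GenBank/FASTA; default: synthetic
    gene_exons: Optional[str] = None
    b_samplings: int = 2000
    n_boot: int = 1000
    raw: dict = field(default_factory=dict)

    def __post_init__(self):
        if any(s.simulate is not None for s in self.strains) and \
                self.seed is None:
            raise PipelineError("config",
                                "seed is required when simulating")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not raw or "strains" not in raw or len(raw["strains"]) != 2:
            raise PipelineError("config", "config needs exactly two strains")
        strains = tuple(
            StrainInput(name=name,
                        simulate=block.get("simulate"),
                        genotypes=block.get("genotypes"))
            for name, block in raw["strains"].items()
        )
        analysis = raw.get("analysis", {})
        return cls(
            out_dir=raw.get("out_dir", "sporemap_out"),
            strains=strains,
            seed=raw.get("seed"),
            markers=raw.get("markers"),
            gene_record=raw.get("gene", {}).get("record"),
            gene_exons=raw.get("gene", {}).get("exons"),
            b_samplings=int(analysis.get("B", 2000)),
            n_boot=int(analysis.get("n_boot", 1000)),
            raw=raw,
        )

    def config_hash(self) -> str:
        raw = dict(self.raw) if self.raw else {
            "seed": self.seed, "strains": [s.name for s in self.strains]}
        raw.pop("out_dir", None)  # hash the analysis, not where it lands
        blob = json.dumps(raw, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
            logger.info("stage %s done in %.2fs", name,
                        time.perf_counter() - t0)
            return out
        return wrapper
    return deco


@_stage("inputs")
def _load_strain(cfg: RunConfig, strain: StrainInput, chroms, seed_offset):
    if strain.genotypes is not None:
        gm = read_genotype_matrix(strain.genotypes)
        return gm, None
    sim = dict(strain.simulate)
    strain_key = sim.pop("strain", strain.name)
    n_meioses = int(sim.pop("n_meioses", 25))
    config = study.sim_config(
        strain_key, n_meioses=n_meioses,
        seed=int(cfg.seed) + seed_offset,
        missing_call_rate=float(sim.pop("missing_call_rate", 0.03)))
    models = {c.chrom_id: study.crossover_model(c.chrom_id, strain_key)
              for c in chroms}
    tetrads, gm = simulate_population(chroms, models, config)
    return gm, tetrads


@_stage("map")
def _map_strain(gm: GenotypeMatrix, mt: MarkerTable):
    maps = {}
    for chrom in mt.frame["chrom_id"].unique():
        sub_mt = mt.for_chrom(chrom)
        present = [m for m in sub_mt.marker_names if m in gm.marker_names]
        if len(present) < 2:
            continue
        maps[chrom] = xo_map.interval_map(gm, sub_mt, chrom_id=chrom)
    return maps


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full analysis; returns a dict of output paths and headline
    numbers, and writes the report bundle under cfg.out_dir."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    chroms = [study.chromosome3(), study.chromosome8()]
    if cfg.markers is not None:
        mt = read_marker_table(cfg.markers)
    else:
        mt = MarkerTable(pd.concat(
            [c.marker_table().frame for c in chroms], ignore_index=True))
    write_marker_table(mt, out / "markers.tsv")

    results: dict = {"strains": {}}
    strain_maps = {}
    for offset, strain in enumerate(cfg.strains):
        gm, tetrads = _load_strain(cfg, strain, chroms, offset)
        write_genotype_matrix(gm, out / f"genotypes_{strain.name}.tsv")
        maps = _map_strain(gm, mt)
        strain_maps[strain.name] = maps
        sres = {"n_spores": gm.shape[0]}
        for chrom, im in maps.items():
            frame = im.to_frame()
            frame.to_csv(out / f"interval_map_{strain.name}_{chrom}.tsv",
                         sep="\t", index=False, float_format="%.6g")
            sres[f"map_length_{chrom}_cM"] = xo_map.map_length(im)
        if tetrads is not None:
            tetrads_to_frame(tetrads).to_csv(
                out / f"tetrads_{strain.name}.tsv", sep="\t", index=False)
            tc = xo_stats.TetradCounts.from_tetrads(tetrads)
            sres["tetrad_counts"] = list(tc.counts)
            sres["total_viability_pct"] = xo_stats.total_viability(tc)
            if tc.total >= 20:
                fit = xo_stats.nd_fit(tc, n_boot=cfg.n_boot,
                                      seed=(cfg.seed or 0) + 1000 + offset)
                sres["nd_fit"] = {"v": fit.v, "d": fit.d, "m": fit.m,
                                  "ci": fit.ci}
            else:
                logger.warning("strain %s: only %d tetrads; skipping the "
                               "nondisjunction fit", strain.name, tc.total)
        results["strains"][strain.name] = sres

    # strain comparison per chromosome
    name_a, name_b = (s.name for s in cfg.strains)
    comparisons = {}
    for chrom in strain_maps[name_a]:
        if chrom not in strain_maps[name_b]:
            continue
        cmp = xo_stats.compare_maps(
            strain_maps[name_a][chrom], strain_maps[name_b][chrom],
            B=cfg.b_samplings, seed=(cfg.seed or 0) + 2000)
        comparisons[chrom] = {
            "total_cM": {name_a: cmp.total_cM_a, name_b: cmp.total_cM_b},
            "whole_chromosome_p": cmp.whole_chromosome_p,
            "distribution_p": cmp.distribution_p,
            "per_interval_p": cmp.per_interval_p,
            "notes": list(cmp.notes),
        }
        cmp.to_frame().to_csv(out / f"comparison_{chrom}.tsv", sep="\t",
                              index=False, float_format="%.6g")
    results["comparisons"] = comparisons

    # tetrad distribution test when both strains were simulated
    tcs = [results["strains"][s.name].get("tetrad_counts")
           for s in cfg.strains]
    if all(tc is not None for tc in tcs):
        results["tetrad_distribution_p"] = xo_stats.tetrad_distribution_test(
            xo_stats.TetradCounts(tuple(tcs[0])),
            xo_stats.TetradCounts(tuple(tcs[1])))

    # allele-effect table
    if cfg.gene_record is not None:
        gene = read_gene_record(cfg.gene_record, cfg.gene_exons)
    else:
        gene = build_reference_gene()
    rows = []
    for name, spec in allele_specs().items():
        eff = annotate_effect(gene, spec)
        rows.append({"allele": name, "kind": eff.kind,
                     "aa_position": eff.aa_position, "ref_aa": eff.ref_aa,
                     "alt_aa": eff.alt_aa,
                     "truncated_length": eff.truncated_length})
    pd.DataFrame(rows).to_csv(out / "allele_effects.tsv", sep="\t",
                              index=False)

    with open(out / "report.json", "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)
    manifest = {
        "package": "sporemap",
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "python": sys.version.split()[0],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results["out_dir"] = str(out)
    return results
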