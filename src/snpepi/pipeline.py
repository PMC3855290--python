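"""End-to-end pipeline: QC -> scan -> threshold -> network -> annotation.

A run is parameterized by :class:`RunConfig` (loadable from a JSON file)
and produces, under the output directory: a QC report, the
significant-pair table, network exports (SIF + attribute tables), a
subnet report (importance / nodes / edges / greatest degree / structure /
chromosomes) and, when interval inputs are supplied, the region and
pathway reports.  "Fixture mode" skips QC and the scan and feeds a
ready-made significant-pair table straight into the network and
annotation stages.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate as ann
from . import io as sio
from . import network as net
from .qc import run_qc
from .scan import bonferroni, run_scan

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {exc}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    Exactly one of (``genotypes`` + ``phenotypes``) or ``pairs_file``
    (fixture mode) must be supplied.
    """

    outdir: str = "snpepi_out"
    genotypes: str | None = None
    genotype_format: str | None = None
    map_file: str | None = None
    phenotypes: str | None = None
    pairs_file: str | None = None
    qtl_file: str | None = None
    gene_file: str | None = None
    pathway_file: str | None = None
    maf_floor: float = 0.05
    max_missing: float = 0.05
    alpha: float = 0.05
    tests_per_pair: int = 4
    threshold: float | None = None
    family_mode: str = "fixed"
    chrom_pairs: list | None = None
    max_pairs: int | None = None
    min_subnet_nodes: int = 3
    half_width: int = ann.DEFAULT_HALF_WIDTH
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        fixture_mode = self.pairs_file is not None
        if not fixture_mode and (self.genotypes is None
                                 or self.phenotypes is None):
            raise ValueError(
                "need genotypes and phenotypes, or pairs_file (fixture mode)")
        for label in ("genotypes", "phenotypes", "pairs_file", "qtl_file",
                      "gene_file", "pathway_file", "map_file"):
            p = getattr(self, label)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{label}: no such file {p!r}")


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages; returns a dict of output paths/tables."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("snpepi")
    root.addHandler(handler)
    root.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    artifacts: dict = {"log": log_path}
    try:
        markers = None
        if config.pairs_file is not None:
            stage = "load-pairs"
            pairs = sio.load_pair_table(config.pairs_file)
            logger.info("fixture mode: %d significant pairs loaded", len(pairs))
            if config.map_file:
                from .containers import MarkerMap
                markers = MarkerMap(pd.read_csv(config.map_file, sep="\t",
                                                dtype={"chrom": str}))
        else:
            stage = "read-inputs"
            gm = sio.read_genotypes(config.genotypes, config.genotype_format,
                                    config.map_file)
            pheno = sio.read_phenotypes(config.phenotypes)
            order = {iid: k for k, iid in enumerate(pheno["id"])}
            missing_ids = [i for i in gm.individuals if i not in order]
            if missing_ids:
                raise ValueError(
                    f"{len(missing_ids)} genotyped individuals lack "
                    f"phenotypes (first: {missing_ids[:3]})")
            pheno = pheno.set_index("id").loc[gm.individuals].reset_index()

            stage = "qc"
            gm, qc_report = run_qc(gm, config.maf_floor, config.max_missing)
            pheno = pheno[pheno["id"].isin(gm.individuals)].reset_index(drop=True)
            (outdir / "qc_report.txt").write_text(qc_report.to_text() + "\n")
            with open(outdir / "qc_report.json", "w") as fh:
                json.dump(qc_report.to_dict(), fh, indent=1)
            artifacts["qc_report"] = qc_report
            logger.info("QC: %d SNPs, %d individuals retained",
                        qc_report.n_snps_out, qc_report.n_individuals_out)

            stage = "scan"
            threshold = config.threshold
            if threshold is None:
                n_tests, threshold = bonferroni(gm.n_snps, config.alpha,
                                                config.tests_per_pair)
                logger.info("Bonferroni: %d tests, threshold %.3g",
                            n_tests, threshold)
            family = pheno["family"].to_numpy() if "family" in pheno else None
            pairs = run_scan(
                gm, pheno["afw"].to_numpy(), family, threshold,
                family_mode=config.family_mode,
                chrom_pairs=config.chrom_pairs, max_pairs=config.max_pairs,
                log=logger.info,
            )
            markers = gm.markers

        stage = "write-pairs"
        artifacts["pairs"] = pairs
        artifacts["pairs_path"] = sio.write_pair_table(
            pairs, outdir / "significant_pairs.tsv")

        stage = "network"
        G = net.build_network(pairs)
        subnets = net.extract_subnets(G, config.min_subnet_nodes)
        summary = net.subnet_summary(subnets)
        summary.to_csv(outdir / "subnets.tsv", sep="\t", index=False)
        artifacts["network"] = G
        artifacts["subnets"] = subnets
        artifacts["subnet_summary"] = summary
        artifacts.update(net.export_network(G, outdir))
        logger.info("network: %d nodes, %d edges, %d subnets (>=%d nodes)",
                    G.number_of_nodes(), G.number_of_edges(), len(subnets),
                    config.min_subnet_nodes)

        if markers is not None:
            stage = "regions"
            snps = [s for s in G.nodes if s in markers]
            skipped = [s for s in G.nodes if s not in markers]
            if skipped:
                logger.warning("%d network SNPs missing from the map; "
                               "excluded from regions", len(skipped))
            frags, unplaced = ann.fragments_for_snps(markers, sorted(snps),
                                                     config.half_width)
            regions = ann.merge_fragments(frags)
            gene_assign = pd.DataFrame(
                columns=["region_chrom", "region_start", "region_end",
                         "region_snps", "gene", "coding"])
            if config.gene_file:
                genes = sio.read_bed(config.gene_file, kind="gene")
                gene_assign = ann.genes_in_regions(regions, genes)
            report = ann.region_report(regions, gene_assign)
            report.to_csv(outdir / "regions.tsv", sep="\t", index=False)
            artifacts["regions"] = regions
            artifacts["region_report"] = report

            if config.qtl_file:
                stage = "qtls"
                qtls = sio.read_bed(config.qtl_file, kind="QTL")
                hits = ann.map_to_qtls(markers, sorted(snps), qtls)
                hits.to_csv(outdir / "qtl_hits.tsv", sep="\t", index=False)
                artifacts["qtl_hits"] = hits

            if config.gene_file and config.pathway_file:
                stage = "pathways"
                mapping = sio.read_gene_pathways(config.pathway_file)
                gene_sets = {}
                node_set = {frozenset(sn.nodes): f"S{k+1}"
                            for k, sn in enumerate(subnets)}
                for nodes, label in node_set.items():
                    sel = gene_assign[gene_assign["region_snps"].map(
                        lambda s: bool(set(s.split(",")) & nodes))]
                    gene_sets[label] = sorted(set(sel["gene"]))
                tally, unmapped = ann.pathway_tally(gene_sets, mapping)
                tally.to_csv(outdir / "pathways.tsv", sep="\t", index=False)
                if unmapped:
                    logger.info("unmapped genes: %s", ", ".join(unmapped))
                artifacts["pathway_tally"] = tally
                artifacts["unmapped_genes"] = unmapped
    except Exception as exc:  # noqa: BLE001 - stage name is the contract
        logger.error("aborting in stage %s: %s", stage, exc)
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise PipelineError(stage, exc) from exc
    finally:
        root.removeHandler(handler)
        handler.close()
    return artifacts
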