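"""End-to-end orchestration with per-stage artifacts and resumability.

Each stage writes its output files plus a JSON report carrying the stage
tallies (reads in/out, unique reads, loci, SSR loci, polymorphic loci,
designed markers) and sha256 checksums of the artifacts. A rerun skips a
stage when its report exists and the checksums still match; a corrupted
artifact halts the run naming the stage.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import catalog as catalog_mod
from . import polymorph, preprocess, primers, ssr_detect

STAGES = ("demux", "stacks", "catalog", "ssr", "cluster", "call", "primers")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    fastq: str
    barcodes: str
    out_dir: str
    seed: int = 0
    remnant: str = preprocess.DEFAULT_REMNANT
    max_barcode_mismatch: int = 1
    window_fraction: float = preprocess.DEFAULT_WINDOW_FRACTION
    min_mean_q: int = preprocess.DEFAULT_MIN_MEAN_Q
    target_length: int = preprocess.DEFAULT_TARGET_LENGTH
    min_depth: int = 2
    merge_distance: int = 2
    catalog_mismatch: int = 0
    ssr_thresholds: dict[int, int] = field(
        default_factory=lambda: {2: 6, 3: 5, 4: 5, 5: 5, 6: 5})
    identity_threshold: float = 0.90
    min_allele_obs: int = 1
    min_support: int = 20
    product_range: tuple[int, int] = (80, 100)
    primer_product_range: tuple[int, int] = (50, 100)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        missing = {"fastq", "barcodes", "out_dir"} - set(raw)
        if missing:
            raise ValueError(f"missing required config keys: {sorted(missing)}")
        if "ssr_thresholds" in raw:
            raw["ssr_thresholds"] = {int(k): int(v)
                                     for k, v in raw["ssr_thresholds"].items()}
        if "product_range" in raw:
            raw["product_range"] = tuple(raw["product_range"])
        if "primer_product_range" in raw:
            raw["primer_product_range"] = tuple(raw["primer_product_range"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _report_path(run_dir: Path, stage: str) -> Path:
    return run_dir / f"stage_{stage}.json"


def _write_report(run_dir: Path, stage: str, counts: dict,
                  artifacts: list[Path]) -> None:
    report = {
        "stage": stage,
        "counts": counts,
        "artifacts": {p.name: _sha256(p) for p in artifacts},
    }
    with open(_report_path(run_dir, stage), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _stage_done(run_dir: Path, stage: str) -> bool:
    """True if the stage can be skipped; raises on checksum mismatch."""
    rp = _report_path(run_dir, stage)
    if not rp.exists():
        return False
    with open(rp) as fh:
        report = json.load(fh)
    for name, digest in report["artifacts"].items():
        path = run_dir / name
        if not path.exists():
            return False
        if _sha256(path) != digest:
            raise StageError(stage, f"artifact {name} failed its checksum; "
                                    "rerun with force=True")
    return True


def run_pipeline(config: RunConfig, force: bool = False) -> Path:
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)

    # ---- demux -----------------------------------------------------------
    if force or not _stage_done(run_dir, "demux"):
        barcode_map = preprocess.BarcodeMap.from_tsv(config.barcodes)
        reads = preprocess.read_fastq(config.fastq)
        by_acc, report = preprocess.process_reads(
            reads, barcode_map,
            remnant=config.remnant,
            max_barcode_mismatch=config.max_barcode_mismatch,
            window_fraction=config.window_fraction,
            min_mean_q=config.min_mean_q,
            target_length=config.target_length,
        )
        artifacts = []
        for accession in sorted(by_acc):
            path = run_dir / f"demux_{accession}.fastq"
            preprocess.write_fastq(by_acc[accession], path)
            artifacts.append(path)
        rpt = run_dir / "filter_report.tsv"
        report.to_tsv(rpt)
        artifacts.append(rpt)
        _write_report(run_dir, "demux", {
            "raw_reads": report.raw,
            "clean_reads": report.retained,
            "discarded_barcode": report.discarded_barcode + report.discarded_ambiguous,
            "discarded_site": report.discarded_site,
            "discarded_quality": report.discarded_quality,
            "discarded_length": report.discarded_length,
            "accessions": len(by_acc),
        }, artifacts)

    # ---- stacks ----------------------------------------------------------
    if force or not _stage_done(run_dir, "stacks"):
        barcode_map = preprocess.BarcodeMap.from_tsv(config.barcodes)
        stacks_by_acc = {}
        for accession in barcode_map.accessions:
            path = run_dir / f"demux_{accession}.fastq"
            acc_reads = [preprocess.GBSRead(r.read_id, r.sequence, r.quality,
                                            accession)
                         for r in preprocess.read_fastq(path)]
            stacks_by_acc[accession] = catalog_mod.build_stacks(
                acc_reads, min_depth=config.min_depth,
                merge_distance=config.merge_distance)
        path = run_dir / "stacks.tsv"
        catalog_mod.write_stacks_tsv(stacks_by_acc, path)
        _write_report(run_dir, "stacks", {
            "unique_stacks": sum(len(v) for v in stacks_by_acc.values()),
            "total_depth": sum(s.depth for v in stacks_by_acc.values()
                               for s in v),
        }, [path])

    # ---- catalog ---------------------------------------------------------
    if force or not _stage_done(run_dir, "catalog"):
        stacks_by_acc = catalog_mod.read_stacks_tsv(run_dir / "stacks.tsv")
        loci = catalog_mod.build_catalog(stacks_by_acc,
                                         catalog_mismatch=config.catalog_mismatch)
        fa, tsv = run_dir / "catalog.fasta", run_dir / "catalog_members.tsv"
        catalog_mod.write_catalog(loci, fa, tsv)
        _write_report(run_dir, "catalog", {"consensus_loci": len(loci)}, [fa, tsv])

    # ---- ssr -------------------------------------------------------------
    if force or not _stage_done(run_dir, "ssr"):
        loci = catalog_mod.read_catalog(run_dir / "catalog.fasta",
                                        run_dir / "catalog_members.tsv")
        thresholds = ssr_detect.SSRThresholds(dict(config.ssr_thresholds))
        hits = []
        for locus in loci:
            hits.extend(ssr_detect.find_perfect_ssrs(
                locus.consensus, thresholds, source_id=f"locus_{locus.locus_id}"))
        misa = run_dir / "misa.tsv"
        ssr_detect.write_misa_tsv(hits, misa)
        summary = ssr_detect.summarize(hits)
        summ = run_dir / "ssr_summary.tsv"
        summary.to_tsv(summ)
        _write_report(run_dir, "ssr", {
            "ssr_hits": len(hits),
            "ssr_loci": len({h.source_id for h in hits}),
        }, [misa, summ])

    # ---- cluster ---------------------------------------------------------
    if force or not _stage_done(run_dir, "cluster"):
        clusters, accessions = _build_clusters(run_dir, config)
        at = run_dir / "allele_table.tsv"
        polymorph.write_allele_table(clusters, accessions, at)
        cf = run_dir / "centroids.fasta"
        polymorph.write_centroids_fasta(clusters, cf)
        _write_report(run_dir, "cluster", {"clusters": len(clusters)}, [at, cf])

    # ---- call ------------------------------------------------------------
    if force or not _stage_done(run_dir, "call"):
        clusters, _ = _build_clusters(run_dir, config)
        rows = []
        n_poly = 0
        for cl in clusters:
            poly, alleles = polymorph.call_polymorphic(cl, config.min_allele_obs)
            n_poly += poly
            rows.append((cl.cluster_id, poly, alleles, cl.support))
        path = run_dir / "polymorphic.tsv"
        with open(path, "w") as fh:
            fh.write("cluster_id\tpolymorphic\talleles\tsupport\n")
            for cid, poly, alleles, support in rows:
                fh.write(f"{cid}\t{int(poly)}\t"
                         f"{','.join(map(str, alleles))}\t{support}\n")
        _write_report(run_dir, "call", {"polymorphic_loci": n_poly,
                                        "clusters": len(rows)}, [path])

    # ---- primers ---------------------------------------------------------
    if force or not _stage_done(run_dir, "primers"):
        clusters, _ = _build_clusters(run_dir, config)
        poly_flags = {}
        with open(run_dir / "polymorphic.tsv") as fh:
            fh.readline()
            for line in fh:
                cid, poly, _, _ = line.rstrip("\n").split("\t")
                poly_flags[int(cid)] = bool(int(poly))
        constraints = primers.PrimerConstraints(
            product_range=config.primer_product_range)
        candidates, primer_rows = [], []
        for cl in clusters:
            if not poly_flags.get(cl.cluster_id):
                continue
            pair, _fails = primers.design_pair(cl, constraints)
            _, alleles = polymorph.call_polymorphic(cl, config.min_allele_obs)
            candidates.append(polymorph.MarkerCandidate(
                cluster=cl, alleles=alleles,
                supporting_accessions=cl.support,
                expected_product_size=pair.product_size if pair else None,
                primer_pair=pair,
            ))
            if pair:
                primer_rows.append((cl.cluster_id, cl.centroid.motif,
                                    cl.centroid.repeat_count, pair))
        selected = polymorph.select_candidates(
            candidates, min_support=config.min_support,
            product_range=config.product_range)
        pt, ct = run_dir / "primers.tsv", run_dir / "candidates.tsv"
        primers.write_primer_table(primer_rows, pt)
        polymorph.write_candidates_tsv(candidates, ct)
        _write_report(run_dir, "primers", {
            "designed_pairs": len(primer_rows),
            "selected_markers": len(selected),
        }, [pt, ct])

    return run_dir


def _build_clusters(run_dir: Path, config: RunConfig):
    """Recreate masked records from the catalog + SSR stage artifacts and
    cluster them (deterministic, so call/primers stages can rebuild)."""
    loci = catalog_mod.read_catalog(run_dir / "catalog.fasta",
                                    run_dir / "catalog_members.tsv")
    thresholds = ssr_detect.SSRThresholds(dict(config.ssr_thresholds))
    records = []
    for locus in loci:
        hits = ssr_detect.find_perfect_ssrs(
            locus.consensus, thresholds, source_id=f"locus_{locus.locus_id}")
        support = tuple(sorted(
            (acc, sum(st.depth for st, _ in lst))
            for acc, lst in locus.members.items()))
        for k, hit in enumerate(hits):
            records.append(polymorph.MaskedRecord(
                source_id=f"locus_{locus.locus_id}.{k}",
                masked=polymorph.mask_ssr(locus.consensus, hit),
                motif=hit.motif,
                repeat_count=hit.repeat_count,
                support=support,
            ))
    clusters = polymorph.cluster_loci(records, config.identity_threshold)
    accessions = sorted({acc for locus in loci for acc in locus.members})
    return clusters, accessions
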