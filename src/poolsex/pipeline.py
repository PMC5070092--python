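"""End-to-end orchestration: detector -> windows -> shared -> CNV -> TFBS -> report.

Stages run in method order, each writing a TSV that its own reader can
re-load, so a run is idempotent and resumable from intermediates.  The
final report is a Table-1-style summary per species: mean F_ST across
polymorphic sites plus counts and per-Mb densities of sex-patterned SNPs,
enriched windows and (when annotations are supplied) missense /
deleterious / synonymous classes, formatted as ``count (density)``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import cnv as cnv_mod
from . import io_formats, sexsnp, shared as shared_mod, tfbs as tfbs_mod, windows as win_mod

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class SpeciesInput:
    name: str
    sync_path: str


@dataclass
class PipelineConfig:
    species_a: SpeciesInput
    species_b: SpeciesInput
    out_dir: str
    detector: sexsnp.DetectorParams = field(default_factory=sexsnp.DetectorParams)
    window_size: int = 10_000
    min_snps_enriched: int = 10
    regions: list[win_mod.Region] = field(default_factory=list)
    chrom_lengths: dict[str, int] = field(default_factory=dict)
    comparisons: list[tuple[str, str]] = field(default_factory=list)
    alpha: float = 0.05
    m: int = 12
    shared_region: str | None = None
    gaps_path: str | None = None
    cnv_tracks: list[str] = field(default_factory=list)
    amp_threshold: float = 0.2
    del_threshold: float = 0.2
    tfbs_fasta: str | None = None
    tfbs_pfm: str | None = None
    tfbs_threshold: float = 0.80
    tfbs_flank_radius: int = 20
    annotations_path: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        regions = [
            # region files/blocks are 1-based inclusive; convert here
            win_mod.Region(
                r["label"], (((r["chrom"], int(r["start"]) - 1, int(r["end"])),))
            )
            for r in raw.get("regions", [])
        ]
        detector = sexsnp.DetectorParams(**raw.get("detector", {}))
        return cls(
            species_a=SpeciesInput(**raw["species_a"]),
            species_b=SpeciesInput(**raw["species_b"]),
            out_dir=raw["out_dir"],
            detector=detector,
            window_size=int(raw.get("window_size", 10_000)),
            min_snps_enriched=int(raw.get("min_snps_enriched", 10)),
            regions=regions,
            chrom_lengths={k: int(v) for k, v in raw.get("chrom_lengths", {}).items()},
            comparisons=[tuple(p) for p in raw.get("comparisons", [])],
            alpha=float(raw.get("alpha", 0.05)),
            m=int(raw.get("m", 12)),
            shared_region=raw.get("shared_region"),
            gaps_path=raw.get("gaps"),
            cnv_tracks=list(raw.get("cnv_tracks", [])),
            amp_threshold=float(raw.get("amp_threshold", 0.2)),
            del_threshold=float(raw.get("del_threshold", 0.2)),
            tfbs_fasta=raw.get("tfbs_fasta"),
            tfbs_pfm=raw.get("tfbs_pfm"),
            tfbs_threshold=float(raw.get("tfbs_threshold", 0.80)),
            tfbs_flank_radius=int(raw.get("tfbs_flank_radius", 20)),
            annotations_path=raw.get("annotations"),
            seed=int(raw.get("seed", 0)),
        )

    def validate(self) -> None:
        for label, path in self._input_paths():
            if not Path(path).exists():
                raise FileNotFoundError(f"{label}: missing input file {path}")
        labels = {r.label for r in self.regions} | {"rest_of_genome"}
        for a, b in self.comparisons:
            for lab in (a, b):
                if lab not in labels:
                    raise ValueError(f"comparison refers to unknown region {lab!r}")
        if self.shared_region is not None and self.shared_region not in labels:
            raise ValueError(f"unknown shared_region {self.shared_region!r}")
        if (self.tfbs_fasta is None) != (self.tfbs_pfm is None):
            raise ValueError("tfbs_fasta and tfbs_pfm must be given together")

    def _input_paths(self) -> list[tuple[str, str]]:
        paths = [
            ("species_a", self.species_a.sync_path),
            ("species_b", self.species_b.sync_path),
        ]
        for opt, label in (
            (self.gaps_path, "gaps"),
            (self.tfbs_fasta, "tfbs_fasta"),
            (self.tfbs_pfm, "tfbs_pfm"),
            (self.annotations_path, "annotations"),
        ):
            if opt is not None:
                paths.append((label, opt))
        paths += [("cnv_track", p) for p in self.cnv_tracks]
        return paths


def read_annotations(path: str | Path) -> dict[tuple[str, int], tuple[str, float | None]]:
    """Effect labels per site: TSV with chrom, pos, effect, provean_score (NA ok)."""
    frame = pd.read_csv(path, sep="\t", na_values="NA")
    out: dict[tuple[str, int], tuple[str, float | None]] = {}
    for row in frame.itertuples(index=False):
        score = None if pd.isna(row.provean_score) else float(row.provean_score)
        out[(row.chrom, int(row.pos))] = (str(row.effect), score)
    return out


def _fmt_cell(count: int, length_bp: int) -> str:
    return f"{count} ({win_mod.density_per_mb(count, length_bp):.2f})"


def make_table1(summaries: Mapping[str, Sequence[win_mod.RegionSummary]]) -> str:
    """Per-species region summary table, one ``count (per-Mb density)`` cell
    per class, plus a totals row of raw counts."""
    header = [
        "region", "mean_fst_polymorphic", "sex_patterned (per Mb)",
        "enriched_windows (per Mb)", "missense (per Mb)",
        "deleterious (per Mb)", "synonymous (per Mb)",
    ]
    lines: list[str] = ["\t".join(header)]
    for species, region_summaries in summaries.items():
        lines.append(f"# {species}")
        totals = {"sex": 0, "enr": 0, "mis": 0, "del": 0, "syn": 0}
        for rs in region_summaries:
            length = rs.region.length_bp
            cc = rs.class_counts or {}
            fst = "NA" if rs.mean_fst_polymorphic is None else f"{rs.mean_fst_polymorphic:.3f}"
            cells = [
                rs.region.label,
                fst,
                _fmt_cell(rs.n_sex_patterned, length),
                _fmt_cell(rs.n_enriched_windows, length),
                _fmt_cell(cc.get("missense", 0), length),
                _fmt_cell(cc.get("deleterious", 0), length),
                _fmt_cell(cc.get("synonymous", 0), length),
            ]
            lines.append("\t".join(cells))
            totals["sex"] += rs.n_sex_patterned
            totals["enr"] += rs.n_enriched_windows
            totals["mis"] += cc.get("missense", 0)
            totals["del"] += cc.get("deleterious", 0)
            totals["syn"] += cc.get("synonymous", 0)
        lines.append(
            "\t".join(
                ["Total", "", str(totals["sex"]), str(totals["enr"]),
                 str(totals["mis"]), str(totals["del"]), str(totals["syn"])]
            )
        )
    return "\n".join(lines) + "\n"


def run_pipeline(
    config: PipelineConfig, dry_run: bool = False, resume: bool = False
) -> list[Path]:
    """Run all stages; returns the list of files written.

    With ``resume`` a stage whose outputs already exist re-reads them
    instead of recomputing.  ``dry_run`` validates the config and touches
    nothing.
    """
    config.validate()
    if dry_run:
        log.info("dry run: config valid")
        return []
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    manifest: dict = {"parameters": {
        "window_size": config.window_size,
        "min_snps_enriched": config.min_snps_enriched,
        "alpha": config.alpha, "m": config.m,
        "amp_threshold": config.amp_threshold,
        "del_threshold": config.del_threshold,
        "tfbs_threshold": config.tfbs_threshold,
        "seed": config.seed,
        "detector": vars(config.detector).copy(),
    }, "counts": {}}

    gaps = io_formats.read_bed_gaps(config.gaps_path) if config.gaps_path else []

    # stage 1: per-species detection -------------------------------------
    stats_by_species: dict[str, list[sexsnp.SiteStats]] = {}
    for sp in (config.species_a, config.species_b):
        out_path = out_dir / f"sitestats_{sp.name}.tsv"
        try:
            sites = io_formats.read_sync_table(sp.sync_path)
            stats = sexsnp.scan_dataset(sites, config.detector)
        except Exception as exc:
            raise StageError(f"find-snps[{sp.name}]: {exc}") from exc
        if not (resume and out_path.exists()):
            sexsnp.write_sitestats(stats, out_path)
        written.append(out_path)
        stats_by_species[sp.name] = stats
        manifest["counts"][f"sites_{sp.name}"] = len(stats)
        manifest["counts"][f"sex_patterned_{sp.name}"] = sum(
            s.is_sex_patterned for s in stats
        )

    # stage 2: windows, region summaries, comparisons --------------------
    region_by_label = {r.label: r for r in config.regions}
    summaries: dict[str, list[win_mod.RegionSummary]] = {}
    tests_frames = []
    try:
        for sp in (config.species_a, config.species_b):
            stats = stats_by_species[sp.name]
            wins = win_mod.window_counts(
                stats, config.window_size, gaps, config.chrom_lengths or None
            )
            win_mod.call_enriched(wins, config.min_snps_enriched)
            wpath = out_dir / f"windows_{sp.name}.tsv"
            io_formats.write_results_tsv(win_mod.windows_to_frame(wins), wpath)
            written.append(wpath)
            regions = list(config.regions)
            if config.chrom_lengths:
                rest = win_mod.Region.complement(config.chrom_lengths, regions)
                regions.append(rest)
                region_by_label[rest.label] = rest
            ann = (
                read_annotations(config.annotations_path)
                if config.annotations_path
                else None
            )
            summaries[sp.name] = [
                win_mod.summarize_region(stats, wins, r, ann) for r in regions
            ]
            if config.comparisons:
                pairs = [
                    (region_by_label[a], region_by_label[b])
                    for a, b in config.comparisons
                ]
                tests = win_mod.compare_regions(wins, pairs, config.alpha, config.m)
                tests.insert(0, "species", sp.name)
                tests_frames.append(tests)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"windows: {exc}") from exc
    if tests_frames:
        tpath = out_dir / "tests.tsv"
        io_formats.write_results_tsv(pd.concat(tests_frames, ignore_index=True), tpath)
        written.append(tpath)

    # stage 3: shared SNPs ------------------------------------------------
    try:
        records = shared_mod.intersect_and_classify(
            stats_by_species[config.species_a.name],
            stats_by_species[config.species_b.name],
        )
        region_of: dict[tuple[str, int], str] = {}
        if config.regions:
            partition, _counts = shared_mod.filter_by_region(records, config.regions)
            for label, recs in partition.items():
                for r in recs:
                    region_of[(r.chrom, r.pos)] = label
        spath = out_dir / "shared.tsv"
        io_formats.write_results_tsv(shared_mod.shared_to_frame(records, region_of), spath)
        written.append(spath)
        manifest["counts"]["shared_snps"] = len(records)
        for cls in (shared_mod.CONSERVED, shared_mod.SWITCHED,
                    shared_mod.SAME_X_DIFF_Y, shared_mod.OTHER):
            manifest["counts"][f"shared_{cls}"] = sum(
                1 for r in records if r.consistency_class == cls
            )
        if config.shared_region:
            region = region_by_label[config.shared_region]
            n_a = sum(
                1 for s in stats_by_species[config.species_a.name]
                if s.is_sex_patterned and region.contains(s.chrom, s.pos - 1)
            )
            n_b = sum(
                1 for s in stats_by_species[config.species_b.name]
                if s.is_sex_patterned and region.contains(s.chrom, s.pos - 1)
            )
            null = shared_mod.expected_shared(n_a, n_b, region.length_bp)
            manifest["null_expectation"] = {
                "n_a": null.n_a, "n_b": null.n_b, "L": null.region_length_bp,
                "expected": null.expected, "expected_rounded": null.expected_rounded,
            }
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"shared: {exc}") from exc

    # stage 4: conserved CNVs ---------------------------------------------
    if len(config.cnv_tracks) >= 2:
        try:
            tracks = []
            for i, path in enumerate(config.cnv_tracks):
                segs = io_formats.read_varscan_segments(path)
                tracks.append(
                    cnv_mod.threshold_segments(
                        segs, config.amp_threshold, config.del_threshold,
                        track_label=f"t{i}",
                    )
                )
            conserved = cnv_mod.conserved_cnvs(tracks)
            cpath = out_dir / "conserved_cnv.tsv"
            io_formats.write_results_tsv(cnv_mod.conserved_to_frame(conserved), cpath)
            written.append(cpath)
            cwins = cnv_mod.cnv_window_density(
                conserved, config.window_size, gaps, config.chrom_lengths or None
            )
            frame = pd.DataFrame(
                [
                    {
                        "chrom": w.chrom, "start": w.start, "end": w.end,
                        "n_cnvs": w.n_cnvs, "effective_len": w.effective_len,
                        "excluded": int(w.excluded),
                        "density_per_mb": w.density_per_mb,
                    }
                    for w in cwins
                ]
            )
            wpath = out_dir / "cnv_windows.tsv"
            io_formats.write_results_tsv(frame, wpath)
            written.append(wpath)
            manifest["counts"]["conserved_cnvs"] = len(conserved)
        except Exception as exc:
            raise StageError(f"cnv: {exc}") from exc

    # stage 5: TFBS allele differences ------------------------------------
    if config.tfbs_fasta and config.tfbs_pfm:
        try:
            from Bio import SeqIO

            seqs = {
                rec.id: str(rec.seq).upper()
                for rec in SeqIO.parse(config.tfbs_fasta, "fasta")
            }
            pwms = [
                tfbs_mod.pfm_to_pwm(p)
                for p in io_formats.read_jaspar_pfm(config.tfbs_pfm)
            ]
            radius = config.tfbs_flank_radius
            rows = []
            for rec in records:
                if rec.chrom not in seqs:
                    continue
                chrom_seq = seqs[rec.chrom]
                lo = max(0, rec.pos - 1 - radius)
                hi = min(len(chrom_seq), rec.pos + radius)
                flank = chrom_seq[lo:hi]
                offset = rec.pos - 1 - lo
                diffs = tfbs_mod.allele_diff(
                    flank, offset, rec.x_a, rec.y_a, pwms,
                    config.tfbs_threshold, radius,
                )
                for d in diffs:
                    if d.status == tfbs_mod.UNCHANGED and d.best_hit_x is None:
                        continue  # no hit with either allele: not reportable
                    rows.append(
                        {
                            "chrom": rec.chrom, "pos": rec.pos,
                            "X": rec.x_a, "Y": rec.y_a,
                            "motif": d.motif_id, "status": d.status,
                            "best_rel_x": None if d.best_hit_x is None
                            else d.best_hit_x.relative_score,
                            "best_rel_y": None if d.best_hit_y is None
                            else d.best_hit_y.relative_score,
                        }
                    )
            apath = out_dir / "allele_diff.tsv"
            io_formats.write_results_tsv(
                pd.DataFrame(
                    rows,
                    columns=["chrom", "pos", "X", "Y", "motif", "status",
                             "best_rel_x", "best_rel_y"],
                ),
                apath,
            )
            written.append(apath)
        except Exception as exc:
            raise StageError(f"tfbs: {exc}") from exc

    # stage 6: report ------------------------------------------------------
    try:
        rpath = out_dir / "report.txt"
        rpath.write_text(make_table1(summaries))
        written.append(rpath)
        mpath = out_dir / "manifest.json"
        mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        written.append(mpath)
    except Exception as exc:
        raise StageError(f"report: {exc}") from exc

    log.info("pipeline complete: %d files in %s", len(written), out_dir)
    return written
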