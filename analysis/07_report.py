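"""Assemble the final per-species region summary report (mean F_ST, counts
and per-Mb densities) in the count-(density) format."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import CHROM_LENGTHS, RESULTS, SIM_DIR, SPECIES_A, SPECIES_B, rest_region, sd_region

from poolsex import io_formats, pipeline, sexsnp, windows

summaries = {}
for name in (SPECIES_A, SPECIES_B):
    sites = io_formats.read_sync_table(SIM_DIR / f"{name}.sync.tsv")
    stats = sexsnp.scan_dataset(sites, sexsnp.DetectorParams())
    gaps = io_formats.read_bed_gaps(SIM_DIR / "gaps.bed")
    wins = windows.window_counts(stats, 10_000, gaps, CHROM_LENGTHS)
    windows.call_enriched(wins, 10)
    summaries[name] = [
        windows.summarize_region(stats, wins, r) for r in (sd_region(), rest_region())
    ]

report = pipeline.make_table1(summaries)
(RESULTS / "report.txt").write_text(report)
print(report)
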