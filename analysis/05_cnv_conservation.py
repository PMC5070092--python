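"""Merge the two VarScan-style comparisons into conserved CNVs and test
whether the sex-determination region is enriched for them."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import CHROM_LENGTHS, RESULTS, SIM_DIR, rest_region, sd_region

from poolsex import cnv, io_formats, windows

tracks = [
    cnv.threshold_segments(
        io_formats.read_varscan_segments(p), amp_threshold=0.2, del_threshold=0.2,
        track_label=f"t{i}",
    )
    for i, p in enumerate(sorted(SIM_DIR.glob("cnv_track_*.copynumber")))
]
conserved = cnv.conserved_cnvs(tracks)
io_formats.write_results_tsv(cnv.conserved_to_frame(conserved), RESULTS / "conserved_cnv.tsv")
print(f"{len(conserved)} conserved CNVs across {len(tracks)} comparisons")

gaps = io_formats.read_bed_gaps(SIM_DIR / "gaps.bed")
cnv_wins = cnv.cnv_window_density(conserved, 10_000, gaps, CHROM_LENGTHS)
region, rest = sd_region(), rest_region()
in_region = [w.n_cnvs for w in cnv_wins
             if not w.excluded and region.contains(w.chrom, (w.start + w.end) / 2)]
in_rest = [w.n_cnvs for w in cnv_wins
           if not w.excluded and rest.contains(w.chrom, (w.start + w.end) / 2)]
u, p = windows.mann_whitney_u(in_region, in_rest)
alpha = windows.bonferroni_alpha(0.05, 12)
print(
    f"conserved-CNV density, SD region vs rest: U={u:.1f}, p={p:.3g} "
    f"-> {'significant' if p < alpha else 'not significant'} at alpha/12 = {alpha}"
)
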