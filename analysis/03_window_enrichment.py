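"""10 kb window densities, enriched-window calls and the Mann-Whitney
comparison of the sex-determination region against the rest of the genome."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import CHROM_LENGTHS, RESULTS, SIM_DIR, SPECIES_A, SPECIES_B, rest_region, sd_region

import pandas as pd

from poolsex import io_formats, sexsnp, windows

gaps = io_formats.read_bed_gaps(SIM_DIR / "gaps.bed")
region, rest = sd_region(), rest_region()

summaries = []
for name in (SPECIES_A, SPECIES_B):
    frame = sexsnp.read_sitestats(RESULTS / f"sitestats_{name}.tsv")
    stats = []
    for row in frame.itertuples(index=False):
        site = io_formats.PooledSiteCount(row.chrom, int(row.pos), row.ref, row.alt, 0, 1, 0, 1)
        s = sexsnp.SiteStats(site=site, evaluated=bool(row.evaluated),
                             is_sex_patterned=bool(row.sex_patterned),
                             fst=None if pd.isna(row.fst) else float(row.fst))
        stats.append(s)
    wins = windows.window_counts(stats, 10_000, gaps, CHROM_LENGTHS)
    windows.call_enriched(wins, min_snps=10)
    io_formats.write_results_tsv(windows.windows_to_frame(wins), RESULTS / f"windows_{name}.tsv")

    for r in (region, rest):
        rs = windows.summarize_region(stats, wins, r)
        summaries.append(
            {"species": name, "region": r.label,
             "mean_fst": rs.mean_fst_polymorphic,
             "n_sex_patterned": rs.n_sex_patterned,
             "density_per_mb": rs.density_per_mb,
             "n_enriched_windows": rs.n_enriched_windows}
        )
    table = windows.compare_regions(wins, [(region, rest)], alpha=0.05, m=12)
    row = table.iloc[0]
    print(
        f"{name}: SD region vs rest, U={row['U']:.1f}, p={row['p']:.3g} "
        f"-> {'significant' if row['significant'] else 'not significant'} "
        f"at alpha/12 = {row['alpha_corrected']}"
    )

frame = pd.DataFrame(summaries)
io_formats.write_results_tsv(frame, RESULTS / "region_summary.tsv")
print(frame.to_string(index=False))
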