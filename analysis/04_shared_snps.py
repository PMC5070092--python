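"""Intersect the two species' sex-patterned SNPs, classify X/Y consistency
and compare the observed shared count with the null expectation n_a*n_b/L."""

import sys
from collections import Counter
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import RESULTS, SIM_DIR, SPECIES_A, SPECIES_B, sd_region

import pandas as pd

from poolsex import io_formats, sexsnp, shared

stats = {}
for name in (SPECIES_A, SPECIES_B):
    sites = io_formats.read_sync_table(SIM_DIR / f"{name}.sync.tsv")
    stats[name] = sexsnp.scan_dataset(sites, sexsnp.DetectorParams())

records = shared.intersect_and_classify(stats[SPECIES_A], stats[SPECIES_B])
region = sd_region()
partition, counts = shared.filter_by_region(records, [region])
region_of = {(r.chrom, r.pos): label for label, recs in partition.items() for r in recs}
io_formats.write_results_tsv(shared.shared_to_frame(records, region_of),
                             RESULTS / "shared_snps.tsv")

classes = Counter(r.consistency_class for r in records)
print(f"shared sex-patterned SNPs: {len(records)} "
      f"({classes[shared.CONSERVED]} conserved X/Y, {classes[shared.SWITCHED]} switched, "
      f"{classes[shared.SAME_X_DIFF_Y]} same-X/different-Y, {classes[shared.OTHER]} other)")
print(f"by region: {counts}")

n_a = sum(1 for s in stats[SPECIES_A]
          if s.is_sex_patterned and region.contains(s.chrom, s.pos - 1))
n_b = sum(1 for s in stats[SPECIES_B]
          if s.is_sex_patterned and region.contains(s.chrom, s.pos - 1))
null = shared.expected_shared(n_a, n_b, region.length_bp)
observed = counts[region.label]
print(f"null expectation in {region.label}: {null.expected_rounded} "
      f"({n_a} x {n_b} / {region.length_bp} bp); observed {observed} "
      f"({observed / null.expected:.1f}x the chance expectation)")
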