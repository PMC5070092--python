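"""Generate the synthetic study inputs: two species' pooled counts with a
shared ancestral sex-determination region, truth tables, CNV tracks, an
assembly-gap BED and a toy reference + motif set for the TFBS stage."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import CHROM_LENGTHS, FATE_FRACTIONS, SEED, SIM_DIR, SPECIES_A, SPECIES_B, sim_config

import numpy as np

from poolsex import io_formats, simulate

SIM_DIR.mkdir(parents=True, exist_ok=True)

(sites_a, truth_a), (sites_b, truth_b), shared_truth = simulate.simulate_species_pair(
    sim_config(SEED), sim_config(SEED + 1), *FATE_FRACTIONS, seed=SEED
)
for name, sites, truth in ((SPECIES_A, sites_a, truth_a), (SPECIES_B, sites_b, truth_b)):
    io_formats.write_sync_table(sites, SIM_DIR / f"{name}.sync.tsv")
    io_formats.write_results_tsv(simulate.truth_to_frame(truth), SIM_DIR / f"{name}.truth.tsv")
    n_sex = sum(1 for t in truth if t.category == simulate.CATEGORY_SEX)
    print(f"{name}: {len(sites)} sites, {n_sex} truth sex-patterned")
print(f"shared ancestral sex-patterned sites: {len(shared_truth)} "
      f"(fates conserved/switched/Y-replaced = {FATE_FRACTIONS})")

# conserved CNVs inside the SD region plus per-track noise elsewhere
true_cnvs = [
    (("LG1", 420_000, 423_000), "AMP"),
    (("LG1", 510_000, 510_600), "DEL"),
    (("LG1", 570_000, 571_500), "AMP"),
]
tracks, _ = simulate.simulate_cnv_tracks(
    2, true_cnvs, noise_rate=6.0, seed=SEED, jitter=0, chrom_lengths=CHROM_LENGTHS
)
for i, track in enumerate(tracks):
    io_formats.write_varscan_segments(track, SIM_DIR / f"cnv_track_{i}.copynumber")
print(f"CNV tracks: {len(tracks)} comparisons, {len(true_cnvs)} true conserved events")

(SIM_DIR / "gaps.bed").write_text("LG1\t0\t2000\nLG1\t700000\t705000\n")

rng = np.random.default_rng(SEED)
seq = "".join(rng.choice(list("ACGT"), size=CHROM_LENGTHS["LG1"]))
with open(SIM_DIR / "ref.fa", "w") as fh:
    fh.write(">LG1\n")
    for i in range(0, len(seq), 80):
        fh.write(seq[i : i + 80] + "\n")
(SIM_DIR / "motifs.jaspar").write_text(
    ">MA0482.1 Gata4-like\n"
    "A [ 0 10  0  0  0 10 ]\n"
    "C [ 0  0  0  0  0  0 ]\n"
    "G [10  0  0  0 10  0 ]\n"
    "T [ 0  0 10 10  0  0 ]\n"
)
print(f"wrote reference FASTA and motif set under {SIM_DIR}")
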