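"""Run the sex-patterned SNP detector on both species and report recovery
against the simulator's truth."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import RESULTS, SIM_DIR, SPECIES_A, SPECIES_B

import pandas as pd

from poolsex import io_formats, sexsnp

params = sexsnp.DetectorParams()  # 0.3-0.7 band, min depth 10, min count 2
for name in (SPECIES_A, SPECIES_B):
    sites = io_formats.read_sync_table(SIM_DIR / f"{name}.sync.tsv")
    stats = sexsnp.scan_dataset(sites, params)
    sexsnp.write_sitestats(stats, RESULTS / f"sitestats_{name}.tsv")

    truth = pd.read_csv(SIM_DIR / f"{name}.truth.tsv", sep="\t")
    truth_sex = set(truth.loc[truth.category == "sex_patterned_Y", "pos"])
    detected = {s.pos for s in stats if s.is_sex_patterned}
    tp = len(detected & truth_sex)
    recall = tp / len(truth_sex) if truth_sex else float("nan")
    precision = tp / len(detected) if detected else float("nan")
    print(
        f"{name}: {len(detected)} sex-patterned of {len(stats)} sites; "
        f"recall {recall:.3f}, precision {precision:.3f} vs truth"
    )
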