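"""Scan the locus for G-quadruplex consensus motifs on both strands.

Uses the G3+N1-7 x4 consensus; overlapping same-strand matches are merged
into loci.  The planted plus-strand instance should be the only locus in the
AT-rich flank.
"""

import argparse
import json
from pathlib import Path

from promscan.g4 import find_g4_hits, merge_hits
from promscan.io import read_fasta

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out-dir", type=Path, default=Path("results"))
args = parser.parse_args()

(record,) = read_fasta(args.out_dir / "locus.fa")
truth = json.loads((args.out_dir / "locus_truth.json").read_text())

hits = find_g4_hits(record)
loci = merge_hits(hits)
with open(args.out_dir / "g4_loci.bed", "w") as fh:
    for locus in loci:
        sig = "G" + "/".join(map(str, locus.best_hit.g_run_lengths)) + \
              ":L" + "/".join(map(str, locus.best_hit.loop_lengths))
        fh.write(f"{record.id}\t{locus.start}\t{locus.end}\t{sig}\t"
                 f"{locus.best_hit.total_g_run}\t{locus.strand}\n")

planted = truth["g4"][0]
print(f"{len(hits)} consensus hit(s) merged into {len(loci)} locus/loci; "
      f"planted G4 at {planted['start']}-{planted['end']} ({planted['strand']})")
for locus in loci:
    print(f"  locus {locus.start}-{locus.end} ({locus.strand}), "
          f"{locus.n_merged_hits} hit(s), best runs {locus.best_hit.g_run_lengths}")
print(f"wrote {args.out_dir}/g4_loci.bed")
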