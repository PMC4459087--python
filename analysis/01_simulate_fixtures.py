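"""Generate the study fixtures: chronogram, calibration table, run grid,
and the eight-locus mechanistic alignment set.

Writes everything under results/fixtures/.  The chronogram is the 17-taxon
aquatic-bird truth tree (root 64 MY, penguin-tubenose split 62 MY, youngest
flamingo split 0.5 MY); alignments are seven 1-kb nuclear loci at the 1 %/MY
pairwise background rate plus a 1.5-kb mitochondrial partition at 5x.
"""

import sys
from pathlib import Path

import satclock as sc
import satclock.io as sio
from satclock.grid import make_run_grid

OUT = Path(__file__).resolve().parents[1] / "results" / "fixtures"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    tree = sc.make_reference_chronogram(SEED)
    sio.write_newick(tree, OUT / "chronogram.nwk")
    sio.write_calibrations(sc.DEFAULT_CALIBRATIONS, OUT / "calibrations.tsv")
    sio.write_run_grid(make_run_grid(SEED), OUT / "run_grid.json")
    for i, locus in enumerate(sc.DEFAULT_LOCI):
        aln = sc.simulate_alignment(tree, locus, seed=SEED + i)
        sio.write_fasta(aln, OUT / f"{locus.name}.fasta")
    print(f"wrote fixture tree ({len(tree.taxa)} taxa, root {tree.root_age} MY), "
          f"{len(sc.DEFAULT_CALIBRATIONS)} calibrations, 45-run grid and "
          f"{len(sc.DEFAULT_LOCI)} alignments to {OUT}")


if __name__ == "__main__":
    main()
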