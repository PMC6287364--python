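#!/usr/bin/env python
"""Optional analysis of real donor/acceptor crystal structures.

Runs the full survey-map-design pipeline on user-supplied PDB files, e.g.
an acid-stable manganese peroxidase donor (PDB 4CZN) against a lignin
peroxidase acceptor (PDB 1B80).  The structures are not bundled with the
package — download them from the PDB first.  Results (bridge counts,
identity/similarity, superposition RMSD, candidate table) depend on
chain selection, pH and survey mode, so no expected values are asserted;
the script prints what it finds.

    python scripts/real_structures.py donor.pdb acceptor.pdb --ph 2.5
"""

from __future__ import annotations

import argparse

from acidbridge.design import run_design_pipeline
from acidbridge.structio import Ensemble, read_pdb


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("donor")
    parser.add_argument("acceptor")
    parser.add_argument("--ph", type=float, default=2.5)
    parser.add_argument("--out", default=None, help="optional candidate CSV path")
    args = parser.parse_args()

    donor = read_pdb(args.donor)
    donor_ens = None
    if isinstance(donor, Ensemble):
        donor_ens, donor = donor, donor.frames[0]
    acceptor = read_pdb(args.acceptor)
    if isinstance(acceptor, Ensemble):
        acceptor = acceptor.frames[0]

    report = run_design_pipeline(
        donor, acceptor, target_ph=args.ph, donor_ensemble=donor_ens)
    for line in report.stage_log:
        print(line)
    print(f"donor bridges: {len(report.donor_bridges)}")
    print(f"conserved: {report.n_conserved}  incompatible: {report.n_incompatible}  "
          f"unmappable: {report.n_unmappable}")
    df = report.to_dataframe()
    if len(df):
        print(df.to_string(index=False))
    if args.out:
        df.to_csv(args.out, index=False)
        print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
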