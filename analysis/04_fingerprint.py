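#!/usr/bin/env python
"""Interaction networks of the docked complex: classify the contacts of the
motif tyrosine and leucine into hydrogen bonds, hydrophobic interactions and
cation-pi interactions.

Reads results/final_complex.pdb (from 03_dock_complex.py) when present,
otherwise fingerprints the reference bound pose.  Writes
results/fingerprints.json.
"""

import json
from pathlib import Path

from pendock.fingerprint import fingerprint_report, fingerprint_residue
from pendock.structure import Structure, parse_structure
from pendock.synth import gen_toy_complex

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    docked = RESULTS / "final_complex.pdb"
    if docked.exists():
        complex_structure = parse_structure(docked)
        source = "docked model (results/final_complex.pdb)"
    else:
        toy = gen_toy_complex(seed=0)
        complex_structure = Structure.concatenate([toy.receptor, toy.ligand])
        source = "reference bound pose"
    print(f"fingerprinting the {source}")

    reports = {}
    for resnum, label in ((536, "motif tyrosine"), (539, "motif leucine")):
        fp = fingerprint_residue(complex_structure, (["R"], ["L"]), ("L", resnum))
        reports[f"L{resnum}"] = fingerprint_report(fp)
        print(f"  {label} (L:{resnum}): {fp.counts}")
        for i in fp.interactions:
            partner = i.partner_of("L", resnum)
            print(f"    {i.kind:11s} -> {partner[2]}{partner[1]:<4d} "
                  f"({i.atoms_a}/{i.atoms_b}, {i.distance:.1f} A)")
    (RESULTS / "fingerprints.json").write_text(json.dumps(reports, indent=2) + "\n")
    print(f"wrote {RESULTS / 'fingerprints.json'}")


if __name__ == "__main__":
    main()
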