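#!/usr/bin/env python
"""Build the canonical incident-matrix fixtures and a study-shaped emulation.

The published analysis reports the marginal counts of the stable-component
factors and their BDeu-smoothed conditionals; those two together determine the
pairwise joint cells exactly, so the 102-record component fixtures here carry
the same sufficient statistics as the original (undeposited) data. The
study-shaped emulation adds independent sparse noise columns for the codes
outside the stable components.

Writes: results/fixtures/{fg,fab,st,nu,full}.csv and results/fixtures/emulated.csv
"""

from pathlib import Path

from bedfallnet.data import marginal_counts, write_incident_matrix
from bedfallnet.synthetic import canonical_fixture, study_emulator

OUT = Path("results/fixtures")
SEED = 17


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for component, name in [
        ("FG", "fg"), ("FAB", "fab"), ("ST", "st"), ("NU", "nu"), ("full", "full")
    ]:
        m = canonical_fixture(component)
        write_incident_matrix(m, OUT / f"{name}.csv")
        print(f"{component:>4}: n={m.n} p={m.p}  positives={marginal_counts(m)}")

    emulated = study_emulator(seed=SEED)
    write_incident_matrix(emulated, OUT / "emulated.csv")
    print(f"emulated study-shape matrix: n={emulated.n} p={emulated.p} (seed={SEED})")


if __name__ == "__main__":
    main()
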