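"""Closed-loop tissue-modulus calibration check.

A synthetic "experiment" is manufactured by solving the phantom FE model at
a known true tissue modulus and converting its stiffness into a noise-free
bending curve; the calibration chain (curve analysis + FE at the 10 GPa
reference + stiffness-ratio back-calculation) must return the true modulus.

    python analysis/02_tissue_modulus_recovery.py

Writes results/modulus_recovery.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from bonefe.validation import modulus_recovery

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    argparse.ArgumentParser(description=__doc__).parse_args()
    rows = []
    for e_true in (6.0, 10.0, 14.0):
        res = modulus_recovery(e_true)
        rows.append(res)
        print(f"E_true {e_true:5.1f} GPa -> recovered "
              f"{res['e_recovered_gpa']:.4f} GPa "
              f"(relative error {res['relative_error']:+.2e})")
    print("recovery is exact up to solver tolerance and curve sampling; the "
          "stiffness ratio cancels every geometric factor.")
    OUT.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(OUT / "modulus_recovery.csv", index=False)
    print(f"wrote {OUT / 'modulus_recovery.csv'}")


if __name__ == "__main__":
    main()
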