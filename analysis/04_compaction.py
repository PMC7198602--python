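"""Compaction arithmetic for the canonical loop and the measured populations.

Converts the UBF-bound region length (15 kb at 0.33 nm/nt) and ring
circumference into the linear compaction factor and the genes-per-loop
interval; evaluated for the canonical 240 nm loop and, when present, for the
population means measured by 03_ring_diameters.py.
Writes results/compaction.json.
"""

import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from nucleoring import compaction_model as cm

OUT = Path(__file__).resolve().parent.parent / "results"


def summarize(diameter_nm: float) -> dict:
    result = cm.compaction_summary(
        cm.CompactionInput(ring_diameter=diameter_nm), compaction_range=(6.0, 7.0)
    )
    return {"ring_diameter_nm": diameter_nm, **asdict(result)}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    payload = {"canonical_240nm": summarize(240.0)}
    for name in ("mef_like", "imr90_like"):
        path = OUT / f"ring_diameters_{name}.csv"
        if path.exists():
            frame = pd.read_csv(path)
            accepted = frame[frame.qc_flag == "ok"]
            if len(accepted):
                payload[name] = summarize(float(accepted.diameter_nm.mean()))
    (OUT / "compaction.json").write_text(json.dumps(payload, indent=2) + "\n")
    canon = payload["canonical_240nm"]
    print(
        f"15 kb at 0.33 nm/nt -> contour {canon['contour_nm']:.0f} nm; "
        f"240 nm loop circumference {canon['circumference_nm']:.1f} nm; "
        f"compaction {canon['compaction_factor']:.2f}-fold"
    )
    lo, hi = canon["genes_per_loop_estimate"]
    print(f"genes per loop at 6-7-fold compaction: {lo:.2f} - {hi:.2f}")
    print(f"full table in {OUT/'compaction.json'}")


if __name__ == "__main__":
    main()
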