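"""Regenerate the fixture x-ray spectra under ``src/pedrsp/data/spectra``.

Run from the repository root:  python scripts/make_spectra.py
"""

from pathlib import Path

import numpy as np

from pedrsp.reference_data import load_cross_sections
from pedrsp.spectra_gen import TUBE_CONFIGS, generate_spectrum

OUT = Path(__file__).resolve().parents[1] / "src" / "pedrsp" / "data" / "spectra"


def main() -> None:
    xs = load_cross_sections()
    OUT.mkdir(parents=True, exist_ok=True)
    for label, cfg in TUBE_CONFIGS.items():
        spec = generate_spectrum(label, cfg["kvp"], cfg["filters"], xs=xs)
        mean_e = float(np.sum(spec.energies * spec.fluence))
        lines = [f"# {label}: tungsten-anode model, {cfg['kvp']:g} kVp, filters {cfg['filters']}"]
        lines += [f"{e:.1f} {f:.8e}" for e, f in zip(spec.energies, spec.fluence)]
        (OUT / f"{label}.txt").write_text("\n".join(lines) + "\n")
        print(f"{label}: {spec.energies.size} bins, mean energy {mean_e:.1f} keV")


if __name__ == "__main__":
    main()
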