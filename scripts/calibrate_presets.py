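#!/usr/bin/env python
"""Print the calibrated constants behind every cell preset.

For each (cell type, genotype, zone) preset this reports the leak
conductance and reversal solved from the target resting potential and input
resistance, the calibrated g_A density (sized so the measured percent
inactivation at +30 mV matches the population mean), and the model's actual
zero-current potential. Useful when adjusting table values or gating
choices.

Usage: python scripts/calibrate_presets.py
"""

import numpy as np

import vestephys as vp
from vestephys import synth


def main() -> None:
    header = (f"{'preset':<24}{'cm pF':>7}{'g_leak nS':>11}{'e_leak mV':>11}"
              f"{'V_rest mV':>11}{'densities nS/pF'}")
    print(header)
    print("-" * len(header))
    for key in synth.preset_keys():
        model = vp.make_preset(*key)
        leak = model["gLeak"]
        v0 = vp.zero_current_potential(model)
        dens = ", ".join(
            f"{c.name}={c.g_max / model.cm:.2f}"
            for c in model.conductances if c.name != "gLeak")
        print(f"{model.label:<24}{model.cm:>7.1f}{leak.g_max:>11.3f}"
              f"{leak.e_rev:>11.1f}{v0:>11.1f}  {dens}")


if __name__ == "__main__":
    main()
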