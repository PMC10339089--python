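"""Convert raw attenuation back to chromophores and saturation.

The forward model and the two inversions are exact inverses on noiseless
data: the modified Beer-Lambert law recovers the concentration *changes*
at the middle transmitter (Tx2, 17.5 mm penetration), and spatially
resolved spectroscopy recovers the absolute saturation from the
attenuation-vs-distance slope.
"""

import numpy as np

import nirskinetics as nk
from nirskinetics.synthetic import QUIET

truth = nk.SimulationTruth(noise=QUIET)
conc = nk.simulate_concentrations(truth, "tibia")
raw = nk.forward_model(conc, nk.TIBIA_DEVICE)

inv = nk.invert_mbll(raw)  # Tx2, µM changes from the first sample
err_o2 = np.abs(inv.o2hb - (conc.o2hb - conc.o2hb[0])).max()
err_hh = np.abs(inv.hhb - (conc.hhb - conc.hhb[0])).max()
print(f"MBLL round trip: max |error| O2Hb {err_o2:.2e} µM, HHb {err_hh:.2e} µM")

tsi, valid = nk.estimate_tsi(raw)  # spatially resolved spectroscopy
print(f"SRS round trip:  max |TSI error| {np.abs(tsi - conc.tsi).max():.2e} %  "
      f"({valid.sum()}/{valid.size} samples valid)")
print("\nBoth errors are at numerical precision: the raw exports carry the")
print("full chromophore and saturation information the pipeline consumes.")
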