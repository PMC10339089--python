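"""Generate a pair of synthetic device exports with known ground truth.

Simulates the four-posture test (5 min supine, 10 min walk, 5 min stand,
5 min supine) for the tibial and gastrocnemius probes with the pre-bed-rest
group-mean kinetics, renders raw two-wavelength, three-distance attenuation
signals with measurement noise and a walking-cadence artifact, and writes
one delimited text export per device.  The two device clocks differ by a
constant offset; six shared event markers allow re-synchronization.
"""

import dataclasses
from pathlib import Path

import nirskinetics as nk

out = Path("scratch/exports")
out.mkdir(parents=True, exist_ok=True)

truth = nk.SimulationTruth(noise=dataclasses.replace(nk.NoiseModel(), rng_seed=7))
for tissue, offset in (("tibia", 0.0), ("gastrocnemius", 3.7)):
    rec = nk.simulate_device_recording(truth, tissue, clock_offset=offset)
    path = nk.write_export(rec, out / f"{tissue}.tsv")
    print(f"{tissue}: {rec.n_samples} samples at "
          f"{rec.device.sample_rate_hz:g} Hz, {len(rec.events)} events -> {path}")

print("\nfirst lines of the tibial export:")
for line in (out / "tibia.tsv").read_text().splitlines()[:11]:
    print(" ", line[:100])
print("\nEach row is one 50 Hz sample: attenuation (OD) per transmitter and")
print("wavelength, the device TSI channel (%), and an event-marker column.")
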