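"""Microplate processing: kinetic traces -> blank-corrected per-animal rates.

Builds a synthetic acetylcholinesterase plate (seven reads at one-minute
intervals, triplicate wells, procedural blanks), reduces each well to an
OLS slope in OD/min, blank-corrects, and averages replicates with a CV
quality flag.
"""

from ibrtools import default_design, generate_plate, generate_study, process_plate

design = default_design(seed=7, n_per_group=3)
table = generate_study(design).set_index("animal_id")
designed = table["AChE"]

plate = generate_plate(design, "AChE", values=designed, noise_sd=0.002, blank_level=0.05)
print(f"plate: {plate['well'].nunique()} wells x {len(plate) // plate['well'].nunique()} reads")

out = process_plate(plate, "AChE", kinetic=True)
print(f"blank rate subtracted: {out.attrs['blank_mean']:.4f} OD/min\n")
print(f"{'animal':>8} {'designed':>9} {'recovered':>10} {'CV':>6}")
for animal in designed.index[:6]:
    print(
        f"{animal:>8} {designed[animal]:9.4f} {out.loc[animal, 'value']:10.4f} "
        f"{out.loc[animal, 'cv']:6.1%}"
    )
print(
    "\nRecovered rates match the designed values to within the injected read "
    "noise; the CV column flags replicate scatter above the 20% threshold."
)
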