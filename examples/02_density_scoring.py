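"""From raw field counts to compartment densities to the Immunoscore.

Each compartment density is the mean of per-field densities over three
selected high-density fields; densities are then dichotomized against the
published cutoffs (490/290/116/70 cells/mm² for CD3_CT/CD3_IM/CD8_CT/
CD8_IM, ties going to "low") and the Immunoscore is the count of "high"
compartments.
"""

from tilscore import (DEFAULT_CUTOFFS, RegionMeasurement, assign_immunoscore,
                      compute_density, dichotomize)
from tilscore.density import Marker, Region

counts = {
    ("CD3", "CT"): [520, 480, 610],
    ("CD3", "IM"): [300, 280, 350],
    ("CD8", "CT"): [90, 110, 95],
    ("CD8", "IM"): [120, 100, 140],
}

calls = {}
for (marker, region), c in counts.items():
    m = RegionMeasurement("P001", Marker(marker), Region(region),
                          area_counts=c, area_mm2=[1.0, 1.0, 1.0])
    density = compute_density(m)
    cutoff = DEFAULT_CUTOFFS[m.compartment]
    calls[m.compartment] = dichotomize(density, cutoff)
    print(f"{m.compartment}: density {density:7.1f} cells/mm², "
          f"cutoff {cutoff:5.0f} -> {calls[m.compartment]}")

grade = assign_immunoscore(calls, patient_id="P001")
print(f"\nImmunoscore: I{grade.grade}")
print("The grade counts the compartments whose density strictly exceeds "
      "its cutoff; here CD8_CT (98.3 <= 116) is the only low compartment, "
      "so the specimen scores I3.")
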