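"""From CSP significance classes to ambiguous docking restraints.

Computes a CSP profile from a simulated titration endpoint, classifies
residues (active > mean + 1 SD; passive between mean and mean + 1 SD;
broadened peaks count as active interface evidence), and writes the
homodimer AIR table that a data-driven docking run would consume.
"""

import io

from ubamap import csp, restraints, synthdata

design = synthdata.TitrationDesign(rng_seed=3, broadened_residues=(408,))
series = synthdata.gen_titration(design)

broad = csp.flag_broadened(series)
endpoint = csp.PeakList()
for key, peak in series.endpoint.peaks.items():
    if key[0] not in broad:
        endpoint[key] = peak
profile = csp.classify_residues(csp.compute_csp(series.reference.peaks, endpoint))

print(f"profile mean/sd: {profile.mean:.4f} / {profile.sd:.4f} ppm")
print(f"broadened      : {sorted(broad)} (classed active)")
print(f"active         : {profile.active}")
print(f"passive        : {profile.passive}")

rs = restraints.derive_airs(profile, symmetric=True)
buf = io.StringIO()
restraints.write_air_table(rs, buf)
table = buf.getvalue()
print(f"\nAIR table: {table.count('assign')} assign blocks, first block:\n")
print(table.split("\n\n")[0])
# Each active residue on one segment is restrained to lie within 2.0 A of
# any active-or-passive residue on the partner segment.
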