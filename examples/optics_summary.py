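"""Derived optical quantities of the nine-well chromatic-focus arm.

Prints the depth of field, the per-colour in-focus depth intervals and
their total span, the Schlieren angular cutoff, the spatial sampling and
field of view, and the space-bandwidth product — the numbers that decide
whether a monolayer sitting somewhere in a well is captured in focus by at
least one LED colour.
"""

from contractile.optics import multiwell_preset, optics_report

cfg = multiwell_preset()
print(optics_report(cfg, image_px=(500, 500), fps=100.0))
print()
print("Each colour focuses at a different depth; a sample anywhere inside")
print("the chromatic depth range is sharp in at least one colour, so no")
print("mechanical focusing is needed.")
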