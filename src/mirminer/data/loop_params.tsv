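# Loop initiation free energies and model constants, kcal/mol at 37 C (v1).
# hairpin/bulge/internal entries are indexed by unpaired-loop size; sizes
# beyond the table extrapolate as dG(n) = dG(max) + lxc * ln(n / max).
param	size	value
hairpin	3	5.40
hairpin	4	5.60
hairpin	5	5.70
hairpin	6	5.40
hairpin	7	6.00
hairpin	8	5.50
hairpin	9	6.40
bulge	1	3.80
bulge	2	2.80
bulge	3	3.20
bulge	4	3.60
bulge	5	4.00
bulge	6	4.40
internal	2	1.70
internal	3	1.80
internal	4	1.70
internal	5	2.00
internal	6	2.20
internal	7	2.30
internal	8	2.40
internal	9	2.50
internal	10	2.60
multiloop_closing	-	3.40
multiloop_branch	-	0.40
multiloop_unpaired	-	0.00
lxc	-	1.08
duplex_init	-	4.09
duplex_mismatch_open	-	1.00
duplex_mismatch_nt	-	0.40
min_hairpin_loop	-	3
max_internal_span	-	30
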