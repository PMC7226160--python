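species	site	state
Acholeplasma_laidlawii	m5U54_tRNA	present
Acholeplasma_laidlawii	m5U1939_23S	present
Acholeplasma_laidlawii	Cm1920_23S	present
Acholeplasma_laidlawii	m3U1915_23S	present
Acholeplasma_laidlawii	m5U747_23S	absent
Mesoplasma_florum	m5U54_tRNA	present
Mesoplasma_florum	m5U1939_23S	present
Mesoplasma_florum	Cm1920_23S	present
Mesoplasma_florum	m3U1915_23S	absent
Mesoplasma_florum	m5U747_23S	absent
Spiroplasma_citri	m5U54_tRNA	absent
Spiroplasma_citri	m5U1939_23S	absent
Spiroplasma_citri	Cm1920_23S	present
Spiroplasma_citri	m3U1915_23S	absent
Spiroplasma_citri	m5U747_23S	absent
Mycoplasma_agalactiae	m5U54_tRNA	absent
Mycoplasma_agalactiae	m5U1939_23S	present
Mycoplasma_agalactiae	Cm1920_23S	absent
Mycoplasma_agalactiae	m3U1915_23S	absent
Mycoplasma_agalactiae	m5U747_23S	absent
Mycoplasma_auris	m5U54_tRNA	absent
Mycoplasma_auris	m5U1939_23S	present
Mycoplasma_auris	Cm1920_23S	absent
Mycoplasma_auris	m3U1915_23S	present
Mycoplasma_auris	m5U747_23S	absent
Mycoplasma_mobile	m5U54_tRNA	absent
Mycoplasma_mobile	m5U1939_23S	not_determined
Mycoplasma_mobile	Cm1920_23S	not_determined
Mycoplasma_mobile	m3U1915_23S	not_determined
Mycoplasma_mobile	m5U747_23S	not_determined
Mycoplasma_capricolum_subsp_capricolum	m5U54_tRNA	absent
Mycoplasma_capricolum_subsp_capricolum	m5U1939_23S	present
Mycoplasma_capricolum_subsp_capricolum	Cm1920_23S	present
Mycoplasma_capricolum_subsp_capricolum	m3U1915_23S	present
Mycoplasma_capricolum_subsp_capricolum	m5U747_23S	absent
Mycoplasma_gallisepticum	m5U54_tRNA	absent
Mycoplasma_gallisepticum	m5U1939_23S	absent
Mycoplasma_gallisepticum	Cm1920_23S	absent
Mycoplasma_gallisepticum	m3U1915_23S	absent
Mycoplasma_gallisepticum	m5U747_23S	absent
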