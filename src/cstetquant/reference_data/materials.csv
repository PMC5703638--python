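material,method,formula,volume_nm3,psv_cm3_per_g,mass_density_g_cm3,solvent_fraction
ribosome,counts_and_volume,,7000,,,0.42
rrna,psv,,,0.569,,
tcp,formula,Ca3(PO4)2,,,3.14,
water,formula,H2O,,,0.93,
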