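# Neutral-loss rearrangement rules.
# columns: ion_modes  exact_mass_da  pattern  loss_formula  max_distance
# ion_modes: "+-" applies in both modes, "+" positive only, "-" negative only.
# pattern names refer to the motif registry in fragrank.rearrangements.
+-	18.0106	OH	H2O	3
+-	27.0109	CN	HCN	3
+-	17.0266	NH2	NH3	3
+-	30.0106	COH	CH2O	3
+	46.0055	COOH	HCOOH	3
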