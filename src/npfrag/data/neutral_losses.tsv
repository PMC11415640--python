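# Frequent CID neutral losses (label <TAB> formula); user-replaceable.
water	H2O
carbon monoxide	CO
carbon dioxide	CO2
methyl radical	CH3
ammonia	NH3
formaldehyde	CH2O
methanol	CH4O
glyoxal	C2H2O2
formic acid	CH2O2
methylglyoxal-like	C3H4O2
C5H8O3	C5H8O3
C6H8O4	C6H8O4
C6H8O5	C6H8O5
deoxyhexose	C6H10O4
hexose	C6H10O5
rutinose	C12H20O9
sulfur trioxide	SO3
phosphoric acid	H3PO4
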