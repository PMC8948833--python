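metabolite_id,display_name,platform_mode,retention_index,mass,pathway
4-acetaminophen sulfate,4-acetaminophen sulfate,neg,1792,230.01287,SULT
4-acetamidophenyl glucuronide,4-acetamidophenyl glucuronide,neg,1400,326.08814,UGT
4-acetamidophenol,4-acetamidophenol,neg,2173.7,150.05605,parent
3-(methylthio) acetaminophen sulfate,3-(methylthio) acetaminophen sulfate *,neg,2265,276.00059,mixed
2-hydroxyacetaminophen sulfate,2-hydroxyacetaminophen sulfate *,neg,1674,246.00778,SULT
2-methoxyacetaminophen glucuronide,2-methoxyacetaminophen glucuronide *,neg,1633,356.0987,UGT
2-methoxyacetaminophen sulfate,2-methoxyacetaminophen sulfate *,neg,1949,260.02343,SULT
3-(N-acetyl-L-cystein-S-yl) acetaminophen,3-(N-acetyl-L-cystein-S-yl) acetaminophen,neg,2094,311.07072,CYP
3-(cystein-S-yl) acetaminophen,3-(cystein-S-yl) acetaminophen *,pos_early,2420,271.07471,CYP
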