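# Biomarker panel definitions: panel name -> marker list.
# These are the shipped defaults; pass --panels to fit-kdm to override.
comprehensive: [sbp, whr, pef, ggt, alb, ldl_ch, hdl_ch, tg, ast, cr, alp, urea, mcv, hba1c, plt]
cardiopulmonary: [sbp, pef]
metabolic: [ldl_ch, hdl_ch, hba1c, tg, whr]
liver: [ast, ggt, alp, alb]
renal: [cr, urea]
immune: [plt, mcv]
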