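# Published coefficients of phenomenological proton-RBE models.
#
# Each model maps (LET_d in keV/um, (alpha/beta)_x in Gy) to the asymptotic
# RBE limits RBE_max (zero dose per fraction) and RBE_min (infinite dose per
# fraction), each linear in LET_d:
#
#   value = c0 + c1 * f(abx) * LET_d
#
# with the alpha/beta dependence f selected by `abx_form`:
#   none          f = 1
#   inverse       f = 1 / abx
#   scaled_inverse f = abx_ref / abx
#   sqrt          f = sqrt(abx)
#
# Coefficients are transcribed verbatim from the cited publications; the test
# suite pins this file by checksum so silent transcription drift fails loudly.
CRB:
  citation: "Carabe-Fernandez A et al. Range of therapeutic proton RBE. Phys Med Biol. 2012;57(5):1159-1172."
  rbe_max: {c0: 0.843, c1: 0.154, abx_form: scaled_inverse, abx_ref: 2.686}
  rbe_min: {c0: 1.09, c1: 0.006, abx_form: scaled_inverse, abx_ref: 2.686}
WDB:
  citation: "Wedenberg M, Lind BK, Hardemark B. A model for the relative biological effectiveness of protons. Acta Oncol. 2013;52(3):580-588."
  rbe_max: {c0: 1.0, c1: 0.434, abx_form: inverse}
  rbe_min: {c0: 1.0, c1: 0.0, abx_form: none}
MNM:
  citation: "McNamara AL, Schuemann J, Paganetti H. A phenomenological relative biological effectiveness (RBE) model for proton therapy. Phys Med Biol. 2015;60(21):8399-8416."
  rbe_max: {c0: 0.99064, c1: 0.35605, abx_form: inverse}
  rbe_min: {c0: 1.1012, c1: -0.0038703, abx_form: sqrt}
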