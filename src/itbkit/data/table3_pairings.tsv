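# Multiplicity and specificity of ligand binding by beta-integrin subunits.
# One row per ECM molecule / ligand; receptors are semicolon-separated
# alpha-beta heterodimer names. Transcribed verbatim, including the
# non-canonical receptor name "αHβ7" (VCAM-1 row), which validation flags
# rather than drops. Known internal discrepancies of the source text, kept
# as printed: the prose claims beta1 pairs with fourteen alpha subunits but
# this table yields 12 distinct alpha partners for beta1; the prose claims
# beta7 binds 3 ligands but 4 rows here mention beta7.
ligand	receptors
Collagens	α1β1;α2β1;α10β1;α11β1
E-Cadherin	αEβ7;α2β1
Endorepellin	α2β1
Endostatin	α5β1
Factor X	αMβ2
Fibronectin	α4β1;α5β1;α8β1;αvβ1;αIIbβ3;αvβ3;αvβ6;α4β7;αMβ2
Fibrinogen	αMβ2;αXβ2;αIIbβ3;αvβ3;αvβ5
ICAM-1, -2, -3, -5	αLβ2
ICAM-3	αDβ2
iC3b	αMβ2;αXβ2
Laminins	α1β1;α2β1;α3β1;α6β1;α6β4;α7β1
MadCAM-1	α4β7
Nephronectin (RGD)	α8β1
Osteopontin	αvβ1;αvβ3;αvβ5
Semaphorin 7A	α1β1
Tenascin-C	α1β1;α8β1;α9β1;αvβ3;αvβ6
TGF-β-LAP (RGD)	αvβ6;αvβ8
Tumastatin	αvβ3
VCAM-1	αDβ2;α4β7;αHβ7
VEGF-C, VEGF-D	α9β1
Vitronectin	αvβ1;α8β1;αvβ3;αvβ5;αvβ8
Von Willebrandt Factor	αIIbβ3;αvβ3
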