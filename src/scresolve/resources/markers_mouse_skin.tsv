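# Canonical marker panel for mouse skin (wound-healing context):
# fibroblast, keratinocyte, T-cell, myeloid, endothelial, mural and
# melanocyte subsets identified by feature-plot inspection.
# Notes on naming as transcribed from the source panel:
#  - the hair-follicle subsets are named inconsistently there (HFH-I vs
#    HFK-I; HFK-II appears twice, once with Vsnl1 and once with Krt79);
#    the two HFK-II rows are merged here because cell-type names must be
#    unique. No renaming intent is guessed.
cell_type	markers
Pan-Fibroblast	Pdgfra,Dpt
Reticular Fibroblast	Pcolce2,Aebp1
Papillary Fibroblast	Tmeff2,Gpc3
Perivascular Fibroblast	Tnmd,Lama2
Pan-Keratinocytes	Krt5,Krt14
Spinous Keratinocytes	Krt1,Mt4
Suprabasal Keratinocytes	Alox12e,Orm1,Krt10
HFH-I	Lgr5
Proliferating Keratinocytes	Mki67
Granular Layer Keratinocytes	Akr1c18
Basal Keratinocytes	Pard6b
HFK-II	Vsnl1,Krt79
General CTL	Cd3d,Cd3e,Cd3g,Nkg7
Activating T cells	Il2rb
Effector T cells	Gzmb
Exhausted T cells	Lag3
Classical Monocytes	Itgam,Ly6c2
Neutrophils	Trem1,C5ar1
M1 Macrophages	Cd86,Il1b,Tnf
Langerhans Cells	Cd207,Alox5
Endothelial Cells	Pecam1,Cdh5
Smooth Muscle Cells	Myoz1,Tcap
Melanocytes	Rapsn
Vascular Smooth Muscle Cells	Lmod1,Pcp4l1
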