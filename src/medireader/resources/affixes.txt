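# Common medical prefixes and suffixes used as categorical term features
# and as building blocks for synthetic pseudo-terms.
# Format: prefix:<affix> or suffix:<affix>, one per line; # comments allowed.
prefix:hyper
prefix:hypo
prefix:brady
prefix:tachy
prefix:cardio
prefix:neuro
prefix:gastro
prefix:hepato
prefix:nephro
prefix:osteo
prefix:derm
prefix:hemo
prefix:hema
prefix:angio
prefix:arthro
prefix:broncho
prefix:cyto
prefix:entero
prefix:myo
prefix:peri
prefix:poly
prefix:pseudo
prefix:anti
prefix:dys
prefix:endo
suffix:itis
suffix:osis
suffix:emia
suffix:oma
suffix:pathy
suffix:ectomy
suffix:ostomy
suffix:otomy
suffix:plasty
suffix:scopy
suffix:graphy
suffix:gram
suffix:algia
suffix:megaly
suffix:penia
suffix:rrhea
suffix:sclerosis
suffix:stenosis
suffix:trophy
suffix:plegia
suffix:pnea
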