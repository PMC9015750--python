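# Medical stop words: generic clinical vocabulary that should never be
# annotated or linked, removed before entity linking. One token per line.
# User-overridable via --stopwords / config.
patient
patients
doctor
doctors
nurse
physician
hospital
clinic
history
normal
abnormal
mild
moderate
severe
acute
chronic
left
right
bilateral
daily
twice
dose
doses
tablet
tablets
mg
ml
exam
examination
visit
follow-up
followup
report
result
results
negative
positive
status
condition
symptom
symptoms
pain
fever
wound
operation
treatment
therapy
care
health
medical
medicine
disease
problem
test
procedure
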