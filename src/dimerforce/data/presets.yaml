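# Built-in single-molecule construct presets.
#
# Rigid-body spans and residue counts follow the published construct
# descriptions: an SR domain is ~110 residues with a ~5 nm folded span; a
# full four-SR rod (including the helical inter-repeat linkers) is ~480
# residues with a ~24 nm span. The looped flexible linker is ~170 residues
# in shear geometry and ~218 residues in unzip geometry; its dimer-imposed
# end-to-end distance is ~24 / 18 / 12 nm for the full-rod / three-SR /
# two-SR shear dimers and ~2 nm for the unzip dimer. Sub-rod spans and
# residue totals scale proportionally (three SRs: 360 aa / 18 nm; two SRs:
# 240 aa / 12 nm); they are editable here.
constructs:
  actn1_shear_full:
    geometry: shear
    n_domains: 4
    rod_residues: 480
    rod_span: 24.0
    loop_residues: 170
    dimer_span_before: 24.0
    dimer_spans_after: [24.0]
    loop_end_to_end_in_dimer: 24.0
  actn4_shear_full:
    geometry: shear
    n_domains: 4
    rod_residues: 480
    rod_span: 24.0
    loop_residues: 170
    dimer_span_before: 24.0
    dimer_spans_after: [24.0]
    loop_end_to_end_in_dimer: 24.0
  actn1_actn4_shear_full:
    geometry: shear
    n_domains: 4
    rod_residues: 480
    rod_span: 24.0
    loop_residues: 170
    dimer_span_before: 24.0
    dimer_spans_after: [24.0]
    loop_end_to_end_in_dimer: 24.0
  actn1_unzip_full:
    geometry: unzip
    n_domains: 4
    rod_residues: 480
    rod_span: 24.0
    loop_residues: 218
    dimer_span_before: 2.0
    dimer_spans_after: [24.0, 24.0]
    loop_end_to_end_in_dimer: 2.0
  actn1_shear_three_sr:
    geometry: shear
    n_domains: 3
    rod_residues: 360
    rod_span: 18.0
    loop_residues: 170
    dimer_span_before: 18.0
    dimer_spans_after: [18.0]
    loop_end_to_end_in_dimer: 18.0
  actn1_shear_two_sr:
    geometry: shear
    n_domains: 2
    rod_residues: 240
    rod_span: 12.0
    loop_residues: 170
    dimer_span_before: 12.0
    dimer_spans_after: [12.0]
    loop_end_to_end_in_dimer: 12.0
  actn1_shear_sr1_sr4:
    geometry: shear
    n_domains: 1
    rod_residues: 120
    rod_span: 5.0
    loop_residues: 170
    dimer_span_before: 5.0
    dimer_spans_after: [5.0]
    loop_end_to_end_in_dimer: 5.0
  entamoeba_shear_two_sr:
    geometry: shear
    n_domains: 2
    rod_residues: 240
    rod_span: 12.0
    loop_residues: 170
    dimer_span_before: 12.0
    dimer_spans_after: [12.0]
    loop_end_to_end_in_dimer: 12.0
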