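# Default induction criteria: named test/control treatment contrasts over the
# expression-atlas column names.  Replicate test treatments (the two fungal
# inocula of the AM criterion) are averaged before the ratio is taken.
# "P-repressed" reads low-phosphate control roots as test and high-phosphate
# roots as control, so a ratio >= threshold means repression by phosphate.
criteria:
  - name: LCM
    test: ["Root LCM arbuscular"]
    control: ["Root LCM cortical"]
  - name: AM
    test:
      - "Root (28dpi) Myc (G. intraradices) 6wk 20 uM P"
      - "Root (28dpi) Myc (G. mosseae) 6wk 20 uM P"
    control: ["Root non-Myc (control) 6wk 20 uM P"]
  - name: dmi3
    test: ["Root DMI3 inoculated with Gigaspora (early contact)"]
    control: ["Root DMI3 control"]
  - name: MF_6h
    test: ["Root WT nsMyc-LCOs 6 h"]
    control: ["Root WT MF control 6 h"]
  - name: MF_24h
    test: ["Root WT nsMyc-LCOs 24 h"]
    control: ["Root WT MF control 24 h"]
  - name: P-repressed
    test: ["Root non-Myc (control) 6wk 20 uM P"]
    control: ["Root non-Myc 6wk 2 mM P"]
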