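# Default promoter cis-elements.  Perfect palindromes are scanned on one
# strand only (the reverse complement is the same sequence); the non-palindromic
# CTTC/MYCS element and its extended form are scanned in both orientations,
# each orientation reported separately.
motifs:
  - name: Myc1
    pattern: GGGGTTCGAACCCC
    orientation: single          # perfect palindrome
  - name: Myc2
    pattern: TGAGCTTAGCTCA
    orientation: single          # odd-center palindrome (free center base)
  - name: GCC-palindrome
    pattern: GCCGGC
    orientation: single          # perfect palindrome
  - name: CTTC
    pattern: CTTGTTC
    orientation: both-separate
  - name: CTTC-extended
    pattern: GACTTGTTC
    orientation: both-separate
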