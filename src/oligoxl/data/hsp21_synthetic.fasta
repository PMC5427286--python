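>hsp21_mature_synthetic Synthetic stand-in for mature chloroplast Hsp21 (184 aa): every published tryptic peptide is placed at its published span; unsequenced stretches are K/R-free filler, not the real sequence.
MQDQRENSIDVVQQGQQKGNQGSSVEKRPQQRLTMDVSPFGLLPDPLSPMRSAMGESAMD
FAMPNAESLMVAMGQESPTGMARAPWDIKEEEHEIKMRFDMPGLSKEDVKISVEDNVLVI
KGEQKKEDSDDSWSGRAVDGETNRLQLPDNCEKDKIKAELKNGVLFITIPKTKVERKVID
VQIQ
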