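>ASC synthetic alpha-satellite consensus, A-box at 35-51
ATCTAGCGAATCAGCATAACTCCAATCAAATGAGTTCGTTTCAAACACTCTGTTTCAGTCTGTGTTATATATGATAAATTGCAAACAAATACGCATAAACTGGATAACAATTTGGCGGAGAGAGATGCGTCGATTTGTGGCTAGTCTGTGGTTAGCCGGACCTACGACTGT
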