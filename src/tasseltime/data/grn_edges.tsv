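source	target	sign	evidence
ID1	ZCN8	+	ID1 promotes the florigen-like ZCN8 signal in leaves
ZCN8	ZMM4	+	ZCN8 acts with DLF1 at the shoot apex to activate ZMM4
DLF1	ZMM4	+	DLF1 (FD-like bZIP) partners the mobile signal to activate ZMM4
VGT1	ZmRAP2.7	-	the early VGT1 allele is a cis-regulatory repressor of ZmRAP2.7
ZmRAP2.7	ZMM4	-	ZmRAP2.7 (AP2-like) represses the floral transition
ZMM4	ZMM4	+	positive autoregulatory feedback reinforcing commitment
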