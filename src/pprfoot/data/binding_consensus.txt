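(C/U)A(C/U)XXX(U/C)XXXXXGGX(C/U)(U/C)(C/U)(U/C)(U/C)(U/C)
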