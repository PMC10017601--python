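surgical,imaging,count
dehiscent,dehiscent,27
dehiscent,intact,2
intact,dehiscent,2
intact,intact,9
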