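item,iconicity
orange,3.50
grapes,3.80
apple,4.10
mouse,3.62
lion,3.92
monkey,4.22
train,4.53
bus,4.23
bicycle,3.93
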