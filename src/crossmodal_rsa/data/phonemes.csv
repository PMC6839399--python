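item,phonemes
orange,ɒ r ɪ n dʒ
grapes,g r eɪ p s
apple,æ p ə l
mouse,m aʊ s
lion,l aɪ ə n
monkey,m ʌ ŋ k i
train,t r eɪ n
bus,b ʌ s
bicycle,b aɪ s ɪ k ə l
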