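paci2018-optimized/paced-1hz:
- -0.073188058787813
- 0.06988317815061997
- 1.481533180277008e-05
- 0.9999999941820559
- 0.00010556359997890185
- 0.9560564214569681
- 0.9999782443870662
- 0.9991136212673501
- 0.020277393252360953
- 0.4265339799751623
- 0.03462974965649204
- 0.7525905366192968
- 0.19461078115347277
- 0.10983092416687847
- 0.07583589626187186
- 0.8267145766750367
- 0.006094610148108978
- 6.9920499041687165
- 0.0031308021175734677
- 0.13076508627939895
- 0.037640370747988636
- 1.4867866474867039e-05
- 0.9930838416735942
paci2018-optimized/spontaneous:
- -0.06118112872632622
- 0.09163598171005208
- 1.8151667373263097e-05
- 0.9999999807700223
- 0.0005749057315789285
- 0.9983998062616324
- 0.9997198628276158
- 0.9989229252647626
- 0.0005982537485419644
- 0.3707843228484789
- 0.063231736722666
- 0.5006294522939847
- 0.31547102806915994
- 0.21558186317843014
- 0.11465359676349053
- 0.6954080505026708
- 0.01111856411724071
- 8.68427168371498
- 0.02971648965470944
- 0.07770521865037931
- 0.02832637171679465
- 0.0009165212109114679
- 0.9999817931945574
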