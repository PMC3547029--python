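   SW   perc perc perc  query      position in query           matching       repeat              position in repeat
score   div. del. ins.  sequence    begin  end    (left)    repeat         class/family      begin  end    (left)     ID

  463   12.3  0.1  0.2  chr1          101    400  (99600) +  AluY           SINE/Alu              1    300    (12)     1
  312    8.0  0.0  0.0  chr1          901   1400  (98600) C  L1MA4          LINE/L1             (5)   5800   5300      2
  220   30.0  1.2  0.3  chr1         2001   2300  (97700) +  MER5A          DNA/hAT-Charlie       1    300     (0)     3
  199   21.5  0.4  0.1  chr1         3001   3600  (96400) +  LTR7           LTR/ERV1              1    600     (0)     4
  150   10.0  0.0  0.0  chr1         4001   4200  (95800) +  Helitron1      RC/Helitron           1    200     (0)     5
this line is malformed and should be skipped
  145   15.0  0.0  0.0  chr2          501    800  (49200) C  MIR            SINE/MIR            (10)    250      1     6
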