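((((T06:443.7305175,T07:443.7305175):150.2933948,(((T30:58.63212557,T31:58.63212557):365.5280931,T08:424.1602186):153.6544724,((T14:370.1712213,T15:370.1712213):177.8259886,(T22:126.8336748,T23:126.8336748):421.163535):29.81748114):16.20922125):5.752724558,(((T02:551.7852413,(((T24:78.43231392,T25:78.43231392):250.1903079,T16:328.6226218):137.3814255,T04:466.0040474):85.7811939):5.276955417,(T26:73.26516594,T27:73.26516594):483.7970308):23.73426355,T01:580.7964603):18.98017653):93.22336321,(((((T32:58.49233187,T33:58.49233187):216.7309029,(T18:192.63497,T19:192.63497):82.58826479):206.0384427,((((T12:394.2482514,T13:394.2482514):6.52829269,T11:400.7765441):72.91399356,((T17:222.9762369,(T20:181.9545999,T21:181.9545999):41.02163698):233.0949615,(T09:424.0192902,T10:424.0192902):32.0519082):17.61933925):5.45664492,T03:479.1471826):2.114494857):76.37238693,(T05:453.0100747,(T34:48.87391607,T35:48.87391607):404.1361586):104.6239897):131.0980299,(T28:60.08649973,T29:60.08649973):628.6455945):4.267905739):27;
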