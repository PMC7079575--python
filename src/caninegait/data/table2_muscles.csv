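muscle,volume_cm3,pennation_deg,optimal_fiber_length_cm,tendon_slack_length_cm,max_isometric_force_N
Adductor longus,1.7,41,2.2,0.7,13.3
Adductor magnus et brevis,35.1,4,3.9,0.5,202.4
Biceps femoris (patellar),13.1,0,5.1,5.5,57.5
Biceps femoris (tibial),13.1,0,4.7,5.0,62.5
Biceps femoris (calcaneal),13.1,0,6.5,6.9,45.5
Extensor digitorum lateralis,0.3,10,0.4,10.0,17.7
Extensor digitorum longus,4.2,2,2.5,9.2,38.0
Flexor digitorum profundus,5.7,33,1.5,11.6,71.7
Flexor digitorum superficialis,3.5,30,1.6,16.8,42.6
Gastrocnemius lateralis,6.7,17,2.5,6.5,57.6
Gastrocnemius medialis,5.0,21,2.1,6.6,50.0
Gemelli,1.0,1,0.7,1.0,30.3
Gluteus medius,26.2,13,3.3,1.3,175.6
Gluteus profundus,2.4,3,2.9,0.5,18.9
Gluteus superficialis,4.7,13,4.4,0.6,23.5
Gracilis,9.4,5,2.8,5.8,76.6
Iliopsoas,16.9,6,2.7,2.0,140.0
Obturator externus,2.0,1,2.2,0.1,20.7
Obturator internus,3.5,0,3.3,1.3,23.9
Pectineus,1.3,8,0.9,2.5,31.5
Peroneus longus,1.0,10,0.7,6.9,30.2
Popliteus,1.1,0,2.0,0.4,12.4
Quadratus femoris,1.8,13,2.3,0.5,28.9
Rectus femoris,10.7,11,3.7,6.8,17.3
Sartorius caudalis,1.8,2,8.9,2.5,4.6
Sartorius cranialis,4.8,3,11.3,0.8,9.5
Semimembranosus (tibial),17.0,0,7.0,0.4,54.5
Semimembranosus (femoral),9.2,0,5.8,0.3,35.6
Semitendinosus,15.6,0,6.3,2.8,55.7
Tensor fascia lata,6.2,12,4.1,6.0,33.5
Tibialis cranialis,3.5,13,2.7,4.0,28.1
Vastus lateralis and intermedius,19.2,10,4.3,4.6,99.0
Vastus medialis,8.2,13,4.1,5.2,43.7
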